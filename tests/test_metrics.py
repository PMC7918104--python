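"""Confusion-matrix arithmetic against brute-force and published values."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mobikit import benchmarks
from mobikit.errors import InputError
from mobikit.metrics import (accuracy, counts_from_rates, marginal_means, mcc,
                             report_from_rates, round_percent, youden)

N_POS, N_NEG = benchmarks.N_POS, benchmarks.N_NEG


@pytest.mark.parametrize("tpr, tnr, expected, places", [
    (0.85, 0.63, 0.48, 2),   # best-performing feature set
    (0.88, 0.24, 0.12, 2),   # timed up-and-go reference
    (0.84, 0.26, 0.10, 1),   # four-duration set
    (1.0, 0.0, 0.0, 9),      # uninformative classifier
])
def test_youden_matches_published_values(tpr, tnr, expected, places):
    assert round(youden(tpr, tnr), places) == pytest.approx(expected)


def test_youden_rejects_out_of_range():
    with pytest.raises(InputError):
        youden(1.2, 0.5)


def test_counts_from_rates_arithmetic():
    assert counts_from_rates(0.5, 0.5, 10, 10) == {
        "tp": 5.0, "fn": 5.0, "tn": 5.0, "fp": 5.0}
    c = counts_from_rates(0.85, 0.63, 32, 8)
    assert c["tp"] == pytest.approx(27.2)
    assert c["fn"] == pytest.approx(4.8)
    assert c["tn"] == pytest.approx(5.04)
    assert c["fp"] == pytest.approx(2.96)
    perfect = counts_from_rates(1.0, 1.0, 32, 8)
    assert perfect == {"tp": 32.0, "fn": 0.0, "tn": 8.0, "fp": 0.0}


def test_accuracy_and_mcc_reproduce_published_cells():
    """Printed per-configuration ACC and summary MCC follow from the rates
    with class sizes 32/8."""
    c = counts_from_rates(0.72, 0.38, N_POS, N_NEG)
    assert round_percent(accuracy(c)) == 65
    c = counts_from_rates(0.85, 0.63, N_POS, N_NEG)
    assert round(mcc(c), 2) == pytest.approx(0.45)
    assert accuracy(counts_from_rates(1, 1, 4, 4)) == 1.0
    assert mcc(counts_from_rates(1, 1, 4, 4)) == 1.0


def test_every_published_accuracy_cell_consistent_with_class_sizes():
    """All 54 grid rows: ACC implied by (TPR, TNR, 32, 8) matches the table."""
    for set_name, grid in benchmarks.GRIDS.items():
        for (n, e, r), (tpr, tnr, acc) in grid.items():
            implied = accuracy(counts_from_rates(tpr / 100, tnr / 100, N_POS, N_NEG))
            assert abs(100 * implied - acc) <= 1.0, (set_name, n, e, r)


def test_mcc_matches_pearson_on_all_small_tables():
    """Brute force: MCC equals the point correlation of label indicators
    over every 2x2 integer table with total <= 12."""
    for tp, fn, tn, fp in itertools.product(range(13), repeat=4):
        total = tp + fn + tn + fp
        if total == 0 or total > 12:
            continue
        counts = {"tp": tp, "fn": fn, "tn": tn, "fp": fp}
        truth = np.array([1] * (tp + fn) + [0] * (tn + fp))
        pred = np.array([1] * tp + [0] * fn + [0] * tn + [1] * fp)
        if truth.std() == 0 or pred.std() == 0:
            assert mcc(counts) == 0.0
        else:
            assert mcc(counts) == pytest.approx(np.corrcoef(truth, pred)[0, 1],
                                                abs=1e-12)


def test_accuracy_brute_force_on_all_small_tables():
    for tp, fn, tn, fp in itertools.product(range(7), repeat=4):
        total = tp + fn + tn + fp
        if total == 0:
            continue
        counts = {"tp": tp, "fn": fn, "tn": tn, "fp": fp}
        truth = np.array([1] * (tp + fn) + [0] * (tn + fp))
        pred = np.array([1] * tp + [0] * fn + [0] * tn + [1] * fp)
        assert accuracy(counts) == pytest.approx((truth == pred).mean())


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.floats(0, 1), st.floats(0, 1), st.integers(1, 50), st.integers(1, 50))
def test_youden_round_trips_through_counts(tpr, tnr, n_pos, n_neg):
    rep = report_from_rates(tpr, tnr, n_pos, n_neg)
    assert rep.j == pytest.approx(tpr + tnr - 1.0, abs=1e-12)
    assert rep.tpr == pytest.approx(tpr, abs=1e-12)
    assert rep.tnr == pytest.approx(tnr, abs=1e-12)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.floats(0, 1), st.floats(0, 1), st.integers(1, 50), st.integers(1, 50))
def test_accuracy_is_prevalence_weighted_rate_mean(tpr, tnr, n_pos, n_neg):
    rep = report_from_rates(tpr, tnr, n_pos, n_neg)
    expected = (tpr * n_pos + tnr * n_neg) / (n_pos + n_neg)
    assert rep.acc == pytest.approx(expected, abs=1e-12)


def test_grid_mean_reproduces_published_summary_rows():
    """The summary table equals the column means of the 18-row grids."""
    for set_name, means in benchmarks.MEAN_RATES.items():
        summary = marginal_means(benchmarks.grid_rows(set_name), "all")[0]
        for rate in ("tpr", "tnr", "acc"):
            assert abs(100 * summary[rate] - means[rate]) <= 1.0, (set_name, rate)


@pytest.mark.parametrize("axis, published", [
    ("neurons", benchmarks.NEURON_MEANS),
    ("epochs", benchmarks.EPOCH_MEANS),
    ("regularisation", benchmarks.REGULARISATION_MEANS),
])
def test_marginal_means_reproduce_published_tables(axis, published):
    """Each published per-axis mean equals the 6-row mean of the grid
    (within 1 percentage point for rounding)."""
    for set_name, rows in published.items():
        got = marginal_means(benchmarks.grid_rows(set_name), axis)
        for row in got:
            level = row[axis]
            for rate, value in zip(("tpr", "tnr", "acc"), rows[level]):
                if (set_name, axis, level, rate) in benchmarks.KNOWN_INCONSISTENT:
                    continue
                assert abs(100 * row[rate] - value) <= 1.0, (set_name, axis, level)


def test_marginal_means_of_identical_rows_is_that_row():
    row = {"neurons": 5, "epochs": 2, "regularisation": False,
           "tpr": 0.8, "tnr": 0.4, "acc": 0.72}
    grid = []
    for n in (5, 7, 10):
        for e in (2, 4, 20):
            for r in (False, True):
                grid.append({**row, "neurons": n, "epochs": e, "regularisation": r})
    out = marginal_means(grid, "all")[0]
    assert out == pytest.approx({"tpr": 0.8, "tnr": 0.4, "acc": 0.72})


def test_incomplete_grid_rejected():
    with pytest.raises(InputError):
        marginal_means([{"neurons": 5, "tpr": 1.0, "tnr": 1.0, "acc": 1.0}], "neurons")
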