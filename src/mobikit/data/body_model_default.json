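{
  "total_mass": 80.0,
  "segments": [
    {"name": "pelvis", "length": 0.2, "mass_fraction": 0.142, "com_offset": 0.5,
     "parent": null, "sensor_id": "L5", "colour": "red",
     "descends": false, "attach": "distal", "flexion_sign": 1.0},
    {"name": "trunk", "length": 0.5, "mass_fraction": 0.43, "com_offset": 0.45,
     "parent": "pelvis", "sensor_id": "C7_TH1", "colour": "blue",
     "descends": false, "attach": "distal", "flexion_sign": 1.0},
    {"name": "thigh_l", "length": 0.44, "mass_fraction": 0.14, "com_offset": 0.41,
     "parent": "pelvis", "sensor_id": "THIGH_L", "colour": "green",
     "descends": true, "attach": "proximal", "attach_offset": [0.0, 0.09, 0.0],
     "flexion_sign": -1.0},
    {"name": "thigh_r", "length": 0.44, "mass_fraction": 0.14, "com_offset": 0.41,
     "parent": "pelvis", "sensor_id": "THIGH_R", "colour": "green",
     "descends": true, "attach": "proximal", "attach_offset": [0.0, -0.09, 0.0],
     "flexion_sign": -1.0},
    {"name": "shank_l", "length": 0.43, "mass_fraction": 0.045, "com_offset": 0.44,
     "parent": "thigh_l", "sensor_id": "SHANK_L", "colour": "orange",
     "descends": true, "attach": "distal", "flexion_sign": 1.0},
    {"name": "shank_r", "length": 0.43, "mass_fraction": 0.045, "com_offset": 0.44,
     "parent": "thigh_r", "sensor_id": "SHANK_R", "colour": "orange",
     "descends": true, "attach": "distal", "flexion_sign": 1.0}
  ]
}
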