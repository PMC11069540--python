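{
  "reference": "Cheng, N.-S. (2008) Formula for the viscosity of a glycerol-water mixture, Ind. Eng. Chem. Res. 47, 3285-3288",
  "validity_celsius": [0.0, 100.0],
  "water_mPas": {"prefactor": 1.790, "c1": -1230.0, "c2": 36100.0, "c3": 360.0},
  "glycerol_mPas": {"prefactor": 12100.0, "c1": -1233.0, "c2": 9900.0, "c3": 70.0},
  "a": {"a0": 0.705, "a1": -0.0017},
  "b": {"b0": 4.9, "b1": 0.036, "a_power": 2.5}
}
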