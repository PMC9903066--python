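{
  "seed": 2024,
  "plate_id": "cytokine_panel",
  "grid": {"f_min_hz": 1000.0, "f_max_hz": 1000000.0, "n_points": 121},
  "loads_ohm": [24000.0, 30000.0, 36000.0],
  "interface_area_cm2": 0.0057,
  "sigma_rel": 0.005,
  "board_sigma_rel": 0.0,
  "chip_cv": 0.1,
  "chip_base": {"r_series_ohm": 25000.0, "r_barrier_ohm": 2000.0, "q_cpe": 5.7e-09, "alpha": 0.95},
  "parasitics": {"r_lead_ohm": 100.0, "c_par_farad": 1e-11},
  "schedule": {
    "baseline_time_min": -6.0,
    "fast_interval_min": 4.0,
    "fast_duration_min": 44.0,
    "slow_interval_min": 64.0,
    "slow_duration_min": 2580.0,
    "endpoint_time_min": 2760.0
  },
  "conditions": [
    {"kind": "control", "dose_ng_ml": 0.0, "n_chips": 4},
    {"kind": "ifng", "dose_ng_ml": 0.1, "n_chips": 5},
    {"kind": "ifng", "dose_ng_ml": 1.0, "n_chips": 5},
    {"kind": "ifng", "dose_ng_ml": 10.0, "n_chips": 5},
    {"kind": "ifng", "dose_ng_ml": 100.0, "n_chips": 5},
    {"kind": "tnfa", "dose_ng_ml": 0.1, "n_chips": 5},
    {"kind": "tnfa", "dose_ng_ml": 1.0, "n_chips": 5},
    {"kind": "tnfa", "dose_ng_ml": 10.0, "n_chips": 5},
    {"kind": "tnfa", "dose_ng_ml": 100.0, "n_chips": 5},
    {"kind": "combo", "dose_ng_ml": 0.1, "n_chips": 5},
    {"kind": "combo", "dose_ng_ml": 1.0, "n_chips": 5},
    {"kind": "combo", "dose_ng_ml": 10.0, "n_chips": 5},
    {"kind": "combo", "dose_ng_ml": 100.0, "n_chips": 5}
  ],
  "fit": {"weighting": "modulus", "multistart": 3, "max_iterations": 200, "tolerance": 1e-12}
}
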