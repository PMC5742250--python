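{
 "intra_heart_fraction": 0.9,
 "n_cells": 189,
 "n_hearts": 11,
 "parameters": {
  "baseline_sl": {
   "distribution": "normal",
   "max": 1.96,
   "mean": 1.78,
   "median": 1.79,
   "min": 1.49,
   "sem": 0.01,
   "total_sd": 0.1375
  },
  "frac_shortening": {
   "distribution": "lognormal",
   "max": 0.124,
   "mean": 0.0431,
   "median": 0.0379,
   "min": 0.0182,
   "sem": 0.0013,
   "total_sd": 0.01787
  },
  "t_peak": {
   "distribution": "lognormal",
   "max": 341.0,
   "mean": 168.0,
   "median": 162.0,
   "min": 101.0,
   "sem": 3.0,
   "total_sd": 41.24
  },
  "tr90": {
   "distribution": "lognormal",
   "max": 693.0,
   "mean": 337.0,
   "median": 314.0,
   "min": 189.0,
   "sem": 8.0,
   "total_sd": 109.98
  }
 },
 "reference": {
  "cont_vel_um_s": {
   "mean": -0.87,
   "sem": 0.02
  },
  "peak_um": {
   "mean": 1.7,
   "sem": 0.01
  },
  "rel_vel_um_s": {
   "mean": 0.98,
   "sem": 0.04
  },
  "tr70_ms": {
   "mean": 263.0,
   "sem": 5.0
  },
  "tr80_ms": {
   "mean": 286.0,
   "sem": 6.0
  }
 }
}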