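{
  "source": "synthetic",
  "seed": 0,
  "window_s": 5.0,
  "stride_s": 2.5,
  "stratified_split": true,
  "run_pso_baseline": false,
  "synth": {
    "fs": 360.0,
    "duration_s": 30.0,
    "n_per_class": 40,
    "noise_sd": 0.05,
    "seed": 0,
    "window_s": 5.0,
    "stride_s": 2.5
  },
  "filter": {"low_hz": 0.5, "high_hz": 40.0, "order": 4, "fs": 360.0},
  "wavelet": {"mother": "db4", "levels": 4},
  "glcm": {"levels": 8, "lag": 1, "symmetric": true},
  "egwo": {
    "num_wolves": 10,
    "max_iter": 10,
    "init_k": 10,
    "knn_k": 5,
    "cv_folds": 5,
    "a_start": 2.0,
    "a_end": 0.0,
    "transfer_steepness": 10.0,
    "seed": 0
  },
  "train": {
    "learning_rate": 0.01,
    "batch_size": 100,
    "epochs": 20,
    "l2": 0.001,
    "dropout": 0.2,
    "hidden_size": 50,
    "seed": 0,
    "early_stop_patience": 6,
    "clip_norm": 1.0
  }
}
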