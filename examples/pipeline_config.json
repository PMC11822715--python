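{
  "seed": 7,
  "out_dir": "protospike_out",
  "log_level": "INFO",
  "stages": [
    {
      "name": "simulate_recording",
      "params": {
        "duration": 400000.0,
        "sample_interval": 1.0,
        "isi_mean": 4285.28,
        "isi_cv": 0.3,
        "amp_mean": 1.91,
        "amp_sd": 0.1,
        "noise_beta": 1.0,
        "noise_rms": 0.02
      }
    },
    {
      "name": "spikes",
      "params": {"detector": {"threshold": 0.1, "min_distance": 0.05}}
    },
    {
      "name": "spectrum",
      "params": {"window_length": 1024, "summary": "mean"}
    },
    {
      "name": "boolean",
      "params": {"thresholds": {"threshold_high": 2.0, "threshold_low": -2.0}}
    }
  ]
}
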