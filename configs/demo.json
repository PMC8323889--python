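{
  "seed": 0,
  "output_dir": "shapeincome_demo",
  "cohort": {"n_subjects": 300, "rings": 16, "segments": 12},
  "embedding": {"epochs": 200, "batch_size": 100, "scan": false},
  "reporting": {"n_boot": 200},
  "estimation": {"bootstrap_B": 200}
}
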