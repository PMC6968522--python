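{
  "n_participants": 8,
  "trials_practice": 20,
  "trials_test": 40,
  "mu": 600.0,
  "sigma": 100.0,
  "tau": 150.0,
  "effect_delta": 100.0,
  "error_rate_A": 0.05,
  "error_rate_B": 0.05,
  "builtin_correction": false,
  "correction_penalty_ms": 400.0,
  "fast_trial_rate": 0.0,
  "slow_trial_rate": 0.0,
  "seed": 202009
}
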