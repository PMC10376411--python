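# Demonstration pipeline on synthetic data: generates a 600-person
# two-wave panel (plus unmatched extras for the sensitivity stage),
# screens at the depression cutoff, and runs every analysis stage at
# demo-friendly sizes. Copy and scale up for real use.
out_dir: clpn_demo_out
seed: 2023
generator:
  n_participants: 600
  n_extra_wave1: 400
  n_extra_wave2: 300
screener_cutoff: 8
estimation:
  # fixed penalty keeps the demo's resampling loops fast; drop this key
  # to select the penalty per node by 10-fold cross-validation
  fixed_lambda: 0.05
nct:
  n_permutations: 200
  estimator: pcor
resampling:
  drop_proportions: [0.1, 0.2, 0.3]
  n_boot_stability: 200
  n_boot_edges: 200
sensitivity:
  enabled: true
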