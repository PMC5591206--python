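# Desk-scale learning-length sweep: success rate s vs r0 at N = 1000
# (L ~ 31.6).  Run with:
#   plastnet sweep --config docs/example_sweep.yaml --out results.csv
#   plastnet plot --in results.csv --x r0_over_L --y s --out results.png
grid:
  r0: [0.01, 0.1, 1.0, 3.0, 10.0, 30.0, 100.0, 300.0]
base:
  n_hidden: 1000
  d0: 2.0
  t_refr: 1
  activation: heaviside
  rule: first10
  t_max: 3000
ensemble_size: 20
base_seed: 1
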