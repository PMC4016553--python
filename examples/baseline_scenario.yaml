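# Baseline scenario: 1,500-patient HCC waiting list, 500 grafts, exponential
# tumor sizes with mean 3.33 cm, 5-year horizon.  delta1 = 0.3 places the
# hazard crossing (and hence the optimal cutoff) near 7 cm.
alpha0: 0.048
alpha1: 2.0
delta1: 0.3
delta2: 0.006
lambda: 0.3
T: 5.0
N: 1500
F: 500
S_M: 5.0
policy:
  s0: 5.0          # Milan rule: transplant only tumors up to S_M
run:
  grid: {start: 0.0, stop: 15.0, step: 0.01}
  reps: 300
  seed: 20260925
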