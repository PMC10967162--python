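label: sct
n: 370
category_probs:
- 0.432
- 0.22
- 0.13
- 0.08
- 0.05
- 0.088
baseline_rate: 0.83
rate_ratios:
- 1.0
- 1.0
- 1.07
- 2.18
- 3.09
- 7.39
theta: 0.66
exposure_model: uniform
exposure_years: 1.0
exposure_range:
- 0.08333333333333333
- 1.0
seed: 0
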