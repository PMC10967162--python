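label: gerico
n: 630
category_probs:
- 0.577
- 0.18
- 0.1
- 0.05
- 0.03
- 0.063
baseline_rate: 0.43
rate_ratios:
- 1.0
- 1.64
- 1.13
- 2.55
- 2.33
- 10.02
theta: 1.06
exposure_model: fixed
exposure_years: 1.0
exposure_range:
- 0.08333333333333333
- 1.0
seed: 0
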