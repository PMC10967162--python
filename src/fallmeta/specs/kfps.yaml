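label: kfps
n: 855
category_probs:
- 0.644
- 0.18
- 0.09
- 0.035
- 0.02
- 0.031
baseline_rate: 0.61
rate_ratios:
- 1.0
- 1.46
- 1.65
- 2.98
- 6.24
- 7.4
theta: 1.18
exposure_model: fixed
exposure_years: 1.0
exposure_range:
- 0.08333333333333333
- 1.0
seed: 0
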