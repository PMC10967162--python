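coefficient,scale,gerico_est,gerico_lo,gerico_hi,sct_est,sct_lo,sct_hi,kfps_est,kfps_lo,kfps_hi,overall_est,overall_lo,overall_hi,tau2,i2
baseline,log,0.43,0.35,0.52,0.83,0.61,1.14,0.61,0.54,0.70,0.59,0.41,0.85,0.088,89.24
prior_falls_1,log,1.64,1.22,2.21,1.00,0.64,1.54,1.46,1.15,1.87,1.41,1.13,1.76,0.013,33.50
prior_falls_2,log,1.13,0.70,1.82,1.07,0.63,1.82,1.65,1.21,2.25,1.33,0.98,1.81,0.026,34.55
prior_falls_3,log,2.55,1.52,4.29,2.18,1.15,4.15,2.98,1.90,4.68,2.64,1.96,3.57,0.000,0.00
prior_falls_4,log,2.33,0.96,5.65,3.09,1.26,7.58,6.24,3.71,10.48,3.89,2.06,7.34,0.169,53.19
prior_falls_5+,log,10.02,6.17,16.27,7.39,3.77,14.46,7.40,4.15,13.20,8.48,6.13,11.74,0.000,0.00
theta,linear,1.06,0.71,1.42,0.66,0.44,0.87,1.18,0.86,1.50,0.94,0.61,1.27,,
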