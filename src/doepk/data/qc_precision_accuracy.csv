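session,nominal_ug_ml,observed_mean_ug_ml,observed_sd_ug_ml,rsd_pct,accuracy_pct
intraday,0.1,0.094,0.002,2.12,94
intraday,0.8,0.781,0.031,3.96,97.62
intraday,1.6,1.592,0.056,3.51,99.50
intraday,2.0,1.985,0.110,5.54,99.25
interday,0.1,0.089,0.007,7.86,89
interday,0.8,0.725,0.038,5.24,90.62
interday,1.6,1.512,0.089,5.88,94.50
interday,2.0,1.920,0.135,7.03,96
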