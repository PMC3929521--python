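parameter,emtricitabine,internal_standard
retention_time_min,4.39,6.58
tailing_factor,1.01,1.13
injection_repeatability_rsd,0.752,0.623
resolution_vs_analyte,,7.32
capacity_factor,5.92,6.30
theoretical_plates,4976,5318
asymmetry,1.23,1.36
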