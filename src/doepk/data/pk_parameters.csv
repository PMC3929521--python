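parameter,free_mean,free_sd,np_mean,np_sd
Cmax_ug_ml,1.696,0.017,1.934,0.041
tmax_h,2.0,0.006,16,0.031
t_half_h,9.366,0.580,32.099,2.194
AUC0_inf_ug_ml_h,14.835,0.450,238.667,10.315
AUMC0_inf_ug_ml_h2,178.32,15.095,22156.689,1243.02
Ke_per_h,0.0741,0.004,0.0215,0.0013
MRT_h,12.0,0.670,94.307,1.950
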