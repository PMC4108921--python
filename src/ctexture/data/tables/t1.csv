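class,white,gray,water_halo,fat_halo,black,ischemia,benign,control
white,0.538,0.115,0.007,0.053,0.000,0.211,0.000,0.076
gray,0.222,0.426,0.010,0.040,0.051,0.235,0.017,0.000
water_halo,0.130,0.257,0.080,0.060,0.240,0.230,0.003,0.000
fat_halo,0.075,0.052,0.035,0.785,0.023,0.030,0.000,0.000
black,0.000,0.028,0.082,0.053,0.773,0.065,0.000,0.000
ischemia,0.224,0.101,0.047,0.034,0.120,0.442,0.015,0.016
benign,0.030,0.343,0.083,0.000,0.147,0.390,0.007,0.000
control,0.123,0.003,0.000,0.000,0.000,0.056,0.000,0.818
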