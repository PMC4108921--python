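class,white,gray,water_halo,fat_halo,black,ischemia,benign,control
white,0.667,0.083,0.000,0.042,0.000,0.167,0.000,0.042
gray,0.208,0.417,0.000,0.042,0.000,0.333,0.000,0.000
water_halo,0.000,0.000,0.000,0.000,0.000,0.000,0.000,1.000
fat_halo,0.000,0.000,0.077,0.923,0.000,0.000,0.000,0.000
black,0.000,0.000,0.042,0.000,0.875,0.083,0.000,0.000
ischemia,0.189,0.094,0.094,0.019,0.094,0.472,0.038,0.000
benign,0.000,0.167,0.167,0.000,0.167,0.500,0.000,0.000
control,0.111,0.000,0.000,0.000,0.000,0.000,0.000,0.889
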