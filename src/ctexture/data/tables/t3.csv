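class,white,gray,water_halo,fat_halo,black,ischemia,benign,control
white,0.594,0.081,0.000,0.051,0.000,0.200,0.000,0.073
gray,0.247,0.393,0.003,0.040,0.047,0.266,0.004,0.000
water_halo,0.080,0.385,0.015,0.050,0.305,0.165,0.000,0.000
fat_halo,0.060,0.018,0.040,0.853,0.005,0.025,0.000,0.000
black,0.000,0.026,0.050,0.040,0.819,0.066,0.000,0.000
ischemia,0.227,0.089,0.049,0.027,0.127,0.446,0.026,0.009
benign,0.010,0.350,0.100,0.000,0.175,0.365,0.000,0.000
control,0.147,0.000,0.000,0.000,0.000,0.010,0.000,0.843
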