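class,white,gray,water_halo,fat_halo,black,ischemia,benign,control
white,0.532,0.113,0.009,0.047,0.000,0.235,0.000,0.064
gray,0.217,0.418,0.020,0.040,0.043,0.241,0.021,0.000
water_halo,0.090,0.280,0.105,0.045,0.250,0.230,0.000,0.000
fat_halo,0.034,0.050,0.056,0.834,0.014,0.012,0.000,0.000
black,0.000,0.016,0.066,0.054,0.811,0.053,0.000,0.000
ischemia,0.195,0.098,0.066,0.027,0.136,0.447,0.022,0.010
benign,0.025,0.345,0.075,0.000,0.190,0.345,0.020,0.000
control,0.180,0.000,0.000,0.000,0.000,0.040,0.000,0.780
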