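class,ischemia,benign,control
ischemia,1,0,0
benign,0.77,0.23,0
control,0,0,1
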