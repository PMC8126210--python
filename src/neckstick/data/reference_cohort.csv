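id,length_C7S2_cm,length_C2C7_cm,height_m,bmi,age_y
P1,49.5,6.1,1.61,23.3,30
P2,52.0,5.1,1.81,23.4,52
P3,48.8,5.3,1.65,20.5,31
P4,53.2,7.7,1.81,27.8,28
P5,51.0,5.5,1.72,23.9,52
P6,53.8,6.5,1.87,25.5,53
P7,47.5,5.1,1.69,21.2,31
P8,49.5,5.0,1.68,26.1,52
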