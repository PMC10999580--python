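label,x_orig,y_orig,z_orig,x_rec,y_rec,z_rec,distance_printed
y_0,0,0,0,0.081,-0.054,0.233,0.253
y_10,0,10,0,-0.326,9.896,0.761,0.834
y_20,0,20,0,0.335,20.407,-0.047,0.529
y_30,0,30,0,0.082,29.736,0.681,0.735
y_40,0,40,0,0.358,39.772,0.790,0.897
y_50,0,50,0,0.010,49.340,0.544,0.855
y_60,0,60,0,-0.107,59.515,0.537,0.731
y_70,0,70,0,0.065,68.782,-0.083,1.223
y_80,0,80,0,-0.388,78.113,-0.326,1.954
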