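label,x_orig,y_orig,z_orig,x_rec,y_rec,z_rec,distance_printed
x_0,0,0,0,0.081,-0.054,0.233,0.253
x_10,10,0,0,10.226,-0.109,0.612,0.661
x_20,20,0,0,19.575,-0.018,0.545,0.691
x_30,30,0,0,29.494,-0.069,0.95,1.079
x_40,40,0,0,40.424,-0.209,0.82,0.947
x_50,50,0,0,49.125,-0.288,0.851,1.254
x_60,60,0,0,59.297,0.276,0.736,1.055
x_70,70,0,0,69.473,0.234,1.481,1.589
x_80,80,0,0,78.617,-0.16,1.16,1.812
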