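label,x_orig,y_orig,z_orig,x_rec,y_rec,z_rec,distance_printed
z_0,0,0,0,0.081,-0.054,0.233,0.253
z_10,0,0,10,-0.846,0.013,10.073,0.849
z_20,0,0,20,0.761,-0.484,20.276,0.943
z_30,0,0,30,-0.592,-0.037,30.397,0.714
z_40,0,0,40,0.468,0.725,40.887,1.245
z_50,0,0,50,-0.39,0.629,49.656,0.816
z_60,0,0,60,0.948,0.932,58.783,1.802
z_70,0,0,70,0.049,-0.827,69.197,1.154
z_80,0,0,80,0.14,0.267,75.965,4.046
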