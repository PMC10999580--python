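label,x_orig,y_orig,z_orig,x_rec,y_rec,z_rec,distance_printed
Ovoid1_1,-9.8,16,-1.7,-9.474,15.841,-2.078,0.524
Ovoid1_2,-10,11.1,-2.5,-9.554,11.088,-2.558,0.450
Ovoid1_3,-10.1,6.2,-3.6,-10.484,6.289,-3.019,0.702
Ovoid1_4,-10.2,1.7,-5.6,-10.234,1.46,-4.897,0.744
Ovoid1_5,-10.3,-1.6,-9.2,-10.163,-1.351,-9.219,0.285
Ovoid2_1,6.455,16.788,-1.249,6.348,16.471,-1.593,0.475
Ovoid2_2,6.208,11.851,-2.005,5.963,11.524,-2.343,0.530
Ovoid2_3,5.975,6.97,-3.044,5.54,7.067,-3.044,0.446
Ovoid2_4,5.787,2.366,-4.944,5.499,2.275,-4.035,0.958
Ovoid2_5,5.719,1.098,-8.473,5.218,0.945,-8.705,0.573
Tandem_1,-0.129,0.64,55.0374,-0.831,0.834,55.586,0.912
Tandem_2,-0.264,1.858,50.19,-0.471,1.951,49.504,0.723
Tandem_3,-0.398,3.077,45.343,-0.378,3.21,44.704,0.653
Tandem_4,-0.533,4.295,40.495,-0.648,4.573,41.092,0.669
Tandem_5,-0.788,5.882,33.174,-0.673,5.66,33.2,0.251
Tandem_6,-1.094,7.234,25.803,-1.161,6.988,26.289,0.549
Tandem_7,-1.394,8.298,18.401,-1.697,8.414,17.817,0.668
Tandem_8,-1.675,8.542,10.911,-1.222,8.633,10.582,0.567
Tandem_9,-1.834,7.703,3.46,-1.511,7.42,3.307,0.456
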