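label,dataset,cell,bleach_width_px,final_fitted_point,fibre_length_um,bleach_position_um,geometry,D_um2_per_s,beta
GFP,1,1,10,500,90.0,45.0,standard,9.3,0.001753
GFP,2,1,20,500,90.0,45.0,standard,8.2,0.001572
GFP,3,2,10,500,90.0,45.0,standard,9.6,0.001502
GFP,4,2,20,500,90.0,45.0,standard,9.6,0.001483
GFP,5,3,10,500,90.0,45.0,standard,6.3,0.002618
GFP,6,3,20,500,90.0,45.0,standard,7.3,0.002503
GFP,7,4,10,500,90.0,45.0,standard,10.2,0.001980
GFP,8,4,20,500,90.0,45.0,standard,12.8,0.001181
GFP,9,5,10,500,90.0,45.0,standard,12.4,0.002358
GFP,10,5,20,500,90.0,45.0,standard,10.2,0.000961
GFP,1,1,10,200,90.0,45.0,standard,11.0,0.002259
GFP,2,1,20,200,90.0,45.0,standard,11.1,0.002861
GFP,3,2,10,200,90.0,45.0,standard,10.6,0.001721
GFP,4,2,20,200,90.0,45.0,standard,9.5,0.001418
GFP,5,3,10,200,90.0,45.0,standard,8.6,0.003959
GFP,6,3,20,200,90.0,45.0,standard,11.5,0.004743
GFP,7,4,10,200,90.0,45.0,standard,9.8,0.001765
GFP,8,4,20,200,90.0,45.0,standard,15.0,0.002000
GFP,9,5,10,200,90.0,45.0,standard,14.4,0.002998
GFP,10,5,20,200,90.0,45.0,standard,11.9,0.001895
GFP,11,6,10,200,90.0,45.0,standard,16.0,0.001196
GFP,12,6,20,200,90.0,45.0,standard,18.4,0.002364
GFP,1,1,10,50,90.0,45.0,standard,10.1,0.000000
GFP,2,1,20,50,90.0,45.0,standard,9.8,0.000000
GFP,3,2,10,50,90.0,45.0,standard,9.4,0.000000
GFP,4,2,20,50,90.0,45.0,standard,8.3,0.000000
GFP,5,3,10,50,90.0,45.0,standard,7.6,0.000000
GFP,6,3,20,50,90.0,45.0,standard,9.9,0.000000
GFP,7,4,10,50,90.0,45.0,standard,9.0,0.000000
GFP,8,4,20,50,90.0,45.0,standard,13.8,0.000000
GFP,9,5,10,50,90.0,45.0,standard,11.5,0.000000
GFP,10,5,20,50,90.0,45.0,standard,11.7,0.000000
GFP,11,6,10,50,90.0,45.0,standard,15.2,0.000000
GFP,12,6,20,50,90.0,45.0,standard,14.5,0.000000
GFP,13,7,8,200,82.0,41.0,measured,13.3,0.001050
GFP,14,7,32,200,82.0,41.0,measured,8.9,0.001208
GFP,15,8,8,200,79.0,40.0,measured,18.5,0.001700
GFP,16,8,32,200,79.0,40.0,measured,10.8,0.002270
GFP,17,9,8,200,83.0,30.0,measured,19.8,0.000616
GFP,18,10,8,200,102.0,44.0,measured,17.1,0.001177
GFP,13,7,8,200,90.0,45.0,standard,13.5,0.001084
GFP,14,7,32,200,90.0,45.0,standard,9.0,0.001231
GFP,15,8,8,200,90.0,45.0,standard,19.3,0.001828
GFP,16,8,32,200,90.0,45.0,standard,11.1,0.002377
GFP,17,9,8,200,90.0,45.0,standard,20.8,0.000828
GFP,18,10,8,200,90.0,45.0,standard,16.9,0.001144
GFP,13,7,8,50,90.0,45.0,standard,10.9,0.000000
GFP,14,7,32,50,90.0,45.0,standard,8.0,0.000000
GFP,15,8,8,50,90.0,45.0,standard,12.9,0.000000
GFP,16,8,32,50,90.0,45.0,standard,9.0,0.000000
GFP,17,9,8,50,90.0,45.0,standard,18.5,0.000000
GFP,18,10,8,50,90.0,45.0,standard,15.2,0.000000
huDysGFP,19,11,8,200,90.0,45.0,standard,10.1,0.005649
huDysGFP,20,11,16,200,90.0,45.0,standard,6.5,0.005012
huDysGFP,21,12,8,200,90.0,45.0,standard,7.2,0.002094
huDysGFP,22,12,16,200,90.0,45.0,standard,5.2,0.001708
huDysGFP,23,13,8,200,90.0,45.0,standard,1.7,0.003047
huDysGFP,24,13,16,200,90.0,45.0,standard,1.8,0.001818
huDysGFP,25,14,8,200,90.0,45.0,standard,9.4,0.008203
huDysGFP,26,15,8,200,90.0,45.0,standard,6.0,0.004196
huDysGFP,27,16,4,200,90.0,45.0,standard,1.4,0.001003
huDysGFP,28,16,10,200,90.0,45.0,standard,1.9,0.000966
huDysGFP,19,11,8,50,90.0,45.0,standard,8.7,0.000000
huDysGFP,20,11,16,50,90.0,45.0,standard,5.2,0.000000
huDysGFP,21,12,8,50,90.0,45.0,standard,6.4,0.000000
huDysGFP,22,12,16,50,90.0,45.0,standard,4.9,0.000000
huDysGFP,23,13,8,50,90.0,45.0,standard,1.5,0.000000
huDysGFP,24,13,16,50,90.0,45.0,standard,1.7,0.000000
huDysGFP,25,14,8,50,90.0,45.0,standard,7.7,0.000000
huDysGFP,26,15,8,50,90.0,45.0,standard,5.1,0.000000
huDysGFP,27,16,4,50,90.0,45.0,standard,1.3,0.000000
huDysGFP,28,16,10,50,90.0,45.0,standard,1.8,0.000000
huDysGFP,29,17,4,200,130.0,62.0,measured,1.7,0.001319
huDysGFP,30,17,10,200,130.0,62.0,measured,1.6,0.001140
huDysGFP,31,18,4,200,124.0,49.0,measured,4.0,0.000757
huDysGFP,32,18,10,200,124.0,49.0,measured,3.9,0.001221
huDysGFP,33,19,4,200,106.0,51.0,measured,5.3,0.001332
huDysGFP,34,19,10,200,106.0,51.0,measured,3.6,0.001408
huDysGFP,35,20,10,200,112.0,31.0,measured,3.4,0.004444
huDysGFP,29,17,4,200,90.0,45.0,standard,1.7,0.001319
huDysGFP,30,17,10,200,90.0,45.0,standard,1.6,0.001140
huDysGFP,31,18,4,200,90.0,45.0,standard,4.0,0.000757
huDysGFP,32,18,10,200,90.0,45.0,standard,3.9,0.001221
huDysGFP,33,19,4,200,90.0,45.0,standard,5.3,0.001332
huDysGFP,34,19,10,200,90.0,45.0,standard,3.6,0.001408
huDysGFP,35,20,10,200,90.0,45.0,standard,3.4,0.004447
huDysGFP,29,17,4,50,90.0,45.0,standard,1.4,0.000000
huDysGFP,30,17,10,50,90.0,45.0,standard,1.6,0.000000
huDysGFP,31,18,4,50,90.0,45.0,standard,3.6,0.000000
huDysGFP,32,18,10,50,90.0,45.0,standard,3.5,0.000000
huDysGFP,33,19,4,50,90.0,45.0,standard,4.0,0.000000
huDysGFP,34,19,10,50,90.0,45.0,standard,3.5,0.000000
huDysGFP,35,20,10,50,90.0,45.0,standard,3.1,0.000000
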