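tip,cell,group,cytoplasm_intensity,fractional_recovery,final_unbleached_minus_bleached,recovery_class
1,1,wild-type,14.59,0.08,0.46,<10 s
2,2,wild-type,5.06,0.07,0.24,<10 s
3,3,wild-type,9.44,0.17,0.12,<20 s
4,4,wild-type,6.51,0.17,0.38,<10 s
5,4,wild-type,8.02,0.30,0.05,<10 s
6,5,wild-type,79.28,0.04,0.22,<10 s
7,6,wild-type,1.78,0.09,0.51,<20 s
8,6,wild-type,1.01,0.12,0.38,<10 s
9,7,wild-type,0.28,0.21,0.13,<10 s
10,8,wild-type,27.46,0.05,0.16,<10 s
11,9,wild-type,12.13,0.08,0.17,<10 s
12,9,wild-type,17.34,0.12,0.40,<10 s
13,10,wild-type,5.09,0.13,0.23,<10 s
14,10,wild-type,2.14,0.03,0.34,<10 s
15,11,wild-type,-0.13,0.13,0.80,<10 s
16,12,wild-type,2.09,0.06,0.17,<10 s
17,12,wild-type,1.94,0.04,0.31,<10 s
18,13,wild-type,5.80,0.03,0.29,<10 s
19,13,wild-type,6.65,-0.04,0.32,<10 s
20,14,wild-type,6.42,0.27,0.31,<10 s
21,14,wild-type,6.87,-0.02,0.35,<10 s
22,15,wild-type,8.96,0.25,0.23,<10 s
23,16,dmd^ta222a/ta222a,11.40,0.42,0.25,<10 s
24,17,dmd^ta222a/ta222a,4.70,0.05,0.35,<10 s
25,17,dmd^ta222a/ta222a,3.81,0.01,0.40,<10 s
26,18,dmd^ta222a/ta222a,6.77,0.33,0.12,<10 s
27,19,dmd^ta222a/ta222a,-0.38,-0.02,0.36,<10 s
28,19,dmd^ta222a/ta222a,-0.60,0.11,0.32,<10 s
29,20,dmd^ta222a/ta222a,4.86,0.12,0.38,<10 s
30,21,dmd^ta222a/ta222a,3.45,0.47,0.24,<10 s
31,21,dmd^ta222a/ta222a,3.60,0.47,0.25,<10 s
32,22,dmd^ta222a/ta222a,7.60,0.39,0.10,<10 s
33,23,dmd^ta222a/ta222a,26.07,0.19,0.18,<10 s
34,24,dmd^ta222a/ta222a,6.08,0.15,0.45,<10 s
35,24,dmd^ta222a/ta222a,8.03,0.07,0.38,no recovery
36,25,dmd^ta222a/ta222a,17.93,0.28,0.22,<10 s
37,26,dmd^ta222a/ta222a,6.21,0.12,0.23,<10 s
38,27,dmd^ta222a/ta222a,5.62,0.07,0.13,<20 s
39,28,dmd^ta222a/ta222a,6.88,0.23,0.22,<10 s
40,29,dmd^ta222a/ta222a,23.05,0.17,0.29,<20 s
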