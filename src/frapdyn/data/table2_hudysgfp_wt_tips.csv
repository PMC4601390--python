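tip,cell,group,cytoplasm_intensity,fractional_recovery,final_unbleached_minus_bleached,recovery_class
1,1,wild-type,5.80,0.24,0.14,<10 s
2,1,wild-type,4.58,0.34,0.23,<10 s
3,2,wild-type,21.58,0.16,0.25,no recovery
4,2,wild-type,21.90,0.46,-0.06,<20 s
5,3,wild-type,8.68,0.28,0.22,<10 s
6,3,wild-type,4.04,0.31,0.14,<10 s
7,4,wild-type,5.94,0.59,0.06,<10 s
8,4,wild-type,15.03,0.64,0.09,<10 s
9,5,wild-type,0.80,0.08,0.31,no recovery
10,5,wild-type,1.81,0.17,0.36,<10 s
11,6,wild-type,0.47,0.11,-0.03,<10 s
12,7,wild-type,-0.08,0.07,0.38,<10 s
13,7,wild-type,0.02,0.08,0.17,<10 s
14,8,wild-type,0.50,0.08,0.13,<10 s
15,8,wild-type,2.02,0.09,-0.03,<10 s
16,9,wild-type,2.22,-0.02,0.10,<10 s
17,10,wild-type,0.73,0.26,0.24,<30 s
18,11,wild-type,1.26,0.10,0.31,<10 s
19,12,wild-type,2.31,0.35,0.07,<30 s
20,12,wild-type,1.63,0.08,0.20,<10 s
21,13,wild-type,3.18,0.41,0.06,<10 s
22,14,wild-type,0.07,0.02,0.24,<10 s
23,15,wild-type,0.93,0.15,0.15,<10 s
24,16,wild-type,0.15,-0.09,0.16,<30 s
25,17,wild-type,11.29,0.34,0.26,>30 s
26,17,wild-type,7.88,0.32,-0.03,<20 s
27,18,wild-type,1.06,-0.01,0.26,<10 s
28,19,wild-type,2.05,0.09,0.22,<20 s
29,20,wild-type,0.99,0.17,0.15,<10 s
30,21,wild-type,0.15,0.02,0.45,<10 s
31,22,wild-type,1.52,0.12,0.28,<20 s
32,22,wild-type,11.86,0.35,0.15,<10 s
33,23,wild-type,3.26,0.28,0.12,<10 s
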