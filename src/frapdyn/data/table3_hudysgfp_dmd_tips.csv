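tip,cell,group,cytoplasm_intensity,fractional_recovery,final_unbleached_minus_bleached,recovery_class
1,,dmd^ta222a/ta222a,51.56,0.12,0.18,<10 s
2,,dmd^ta222a/ta222a,23.12,0.10,0.31,<10 s
3,,dmd^ta222a/ta222a,38.04,0.07,0.25,no recovery
4,,dmd^ta222a/ta222a,83.99,0.25,0.02,<10 s
5,,dmd^ta222a/ta222a,4.46,0.06,0.30,<10 s
6,,dmd^ta222a/ta222a,0.34,-0.01,0.21,<10 s
7,,dmd^ta222a/ta222a,3.16,0.21,0.17,<20 s
8,,dmd^ta222a/ta222a,16.49,0.16,0.24,<10 s
9,,dmd^ta222a/ta222a,18.67,0.06,0.07,<10 s
10,,dmd^ta222a/ta222a,8.73,0.20,0.25,<10 s
11,,dmd^ta222a/ta222a,7.12,0.47,0.12,<20 s
12,,dmd^ta222a/ta222a,11.06,0.17,0.15,<20 s
13,,dmd^ta222a/ta222a,10.65,0.09,0.23,<10 s
14,,dmd^ta222a/ta222a,28.41,0.02,0.13,<20 s
15,,dmd^ta222a/ta222a,8.91,0.17,0.14,<10 s
16,,dmd^ta222a/ta222a,41.16,0.24,0.16,<10 s
17,,dmd^ta222a/ta222a,17.71,0.36,0.50,<20 s
18,,dmd^ta222a/ta222a,20.43,0.25,0.36,<10 s
19,,sibling,30.85,-0.02,0.20,<10 s
20,,sibling,45.81,0.12,0.17,<30 s
21,,sibling,13.89,0.11,0.23,<10 s
22,,sibling,7.05,0.10,0.33,<10 s
23,,sibling,12.78,0.01,0.32,<10 s
24,,sibling,6.48,0.09,0.26,<10 s
25,,sibling,10.95,0.07,0.28,<10 s
26,,sibling,8.35,0.20,0.22,<10 s
27,,sibling,10.14,0.15,0.15,<10 s
28,,sibling,7.15,0.11,0.50,<10 s
29,,sibling,7.77,0.06,0.57,<10 s
30,,sibling,19.64,0.16,0.18,<10 s
31,,sibling,16.08,0.32,0.36,<10 s
32,,sibling,8.11,0.13,0.37,<10 s
33,,sibling,7.30,0.20,0.36,<10 s
34,,sibling,14.99,0.40,0.06,<20 s
35,,sibling,29.82,0.28,0.06,<20 s
36,,sibling,9.95,0.34,0.18,<10 s
37,,sibling,32.10,-0.02,0.12,<10 s
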