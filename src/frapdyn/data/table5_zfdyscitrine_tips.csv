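tip,cell,group,cytoplasm_intensity,fractional_recovery,final_unbleached_minus_bleached,recovery_class
1,,heat shock,1.71,-0.04,0.37,<20 s
2,,heat shock,1.85,0.15,0.14,<20 s
3,,heat shock,0.37,0.10,0.39,<20 s
4,,heat shock,3.52,0.09,0.14,<30 s
5,,heat shock,0.98,0.13,0.17,<20 s
6,,heat shock,0.87,0.07,0.21,<20 s
7,,heat shock,1.30,0.13,0.17,<10 s
8,,48 hpf,4.30,0.05,0.36,<10 s
9,,48 hpf,3.11,0.04,0.37,<10 s
10,,48 hpf,1.72,0.12,0.53,<20 s
11,,48 hpf,2.09,0.04,0.39,<20 s
12,,48 hpf,2.01,0.07,0.42,<10 s
13,,48 hpf,6.21,-0.02,0.41,<10 s
14,,40 hpf,3.26,0.10,0.27,<20 s
15,,40 hpf,0.72,0.14,0.25,<30 s
16,,40 hpf,3.57,0.03,0.26,<20 s
17,,40 hpf,4.95,0.08,0.22,<20 s
18,,40 hpf,0.79,0.01,0.25,<10 s
19,,40 hpf,0.09,0.03,0.28,<20 s
20,,30 hpf,1.53,0.07,0.38,<10 s
21,,30 hpf,1.60,0.06,0.48,<60 s
22,,30 hpf,5.02,0.09,0.50,<20 s
23,,30 hpf,2.66,0.09,0.64,<40 s
24,,30 hpf,3.04,0.11,0.44,<10 s
25,,30 hpf,3.19,0.07,0.37,<10 s
26,,30 hpf,2.78,0.03,0.28,<10 s
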