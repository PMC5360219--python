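age,rate_per_100py
60,0.08
65,0.17
70,0.35
75,0.71
80,1.44
85,2.92
90,5.95
95,12.10
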