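age_lo,age_hi,rate_per_100k
20,25,1.5
25,30,7.8
30,35,26.1
35,40,52.4
40,45,95.6
45,50,136.9
50,55,160.2
55,60,178.5
60,65,199.7
65,70,219.3
70,75,229.8
75,80,238.4
80,85,244.9
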