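age,remaining_le
0,86.59
1,85.77
5,81.84
10,76.86
15,71.90
20,66.97
25,62.05
30,57.15
35,52.26
40,47.39
45,42.57
50,37.84
55,33.21
60,28.67
65,24.24
70,19.94
75,15.85
80,12.08
85,8.79
90,6.16
95,4.17
100,2.74
105,1.76
110,1.11
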