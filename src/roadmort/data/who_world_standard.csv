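age_group,weight
0-4,0.088569000850
5-9,0.086869595642
10-14,0.085969910531
15-19,0.084670365372
20-24,0.082171240066
25-29,0.079272254711
30-34,0.076073374319
35-39,0.071474983756
40-44,0.065876943070
45-49,0.060378867396
50-54,0.053681211576
55-59,0.045484080572
60-64,0.037186984555
65-69,0.029589643625
70-74,0.022092267706
75-79,0.015194681861
80-84,0.009096816114
85+,0.006347778278
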