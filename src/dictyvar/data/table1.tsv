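sample	snp_count	avg_depth
ancestor	0
1	0	128
1-NF2	0	43
2	1	137
3	0	146
3-NF1	1	127
4	0	171
5	0	161
5-NF2	3	40
6	1	152
7	4	229
7-NF2	5	44
8	0	165
8-NF1	0	89
9	1	220
9-NF3	1	24
10	1	151
10-NF3	1	23
11	2	116
11-NF1	0	37
12	1	215
12-NF1	1	97
13	1	165
13-NF2	1	70
14	0	127
14-NF3	0	22
15	0	176
15-NF1	0	69
16	0	277
16-NF2	3	118
17	3	123
18	0	191
18-NF1	3	30
19	0	319
19-NF1	0	80
20	0	231
20-NF1	1	66
20-NF3	1	32
21	1	272
21-NF1	3	40
21-NF2	5	45
22	3	291
23	0	305
23-NF1	0	25
23-NF2	0	43
24	0	222
24-NF1	1	32
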