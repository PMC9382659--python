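# 19-nt concatenated duplex worked example; molecule 1 = positions 1-9 (strand break 9)
1 C 0
2 A 8
3 G 7
4 C 15
5 C 14
6 U 0
7 C 3
8 U 2
9 G 0
10 A 18
11 U 17
12 G 16
13 U 0
14 G 5
15 U 4
16 C 12
17 A 11
18 U 10
19 C 0
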