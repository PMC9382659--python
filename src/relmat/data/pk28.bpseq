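# 28-nt pseudoknotted worked example: two stacked helices plus a crossing helix pair
1 G 7
2 A 6
3 U 0
4 G 0
5 U 0
6 G 2
7 U 1
8 C 11
9 A 0
10 U 0
11 C 8
12 A 24
13 G 23
14 A 17
15 C 0
16 C 0
17 U 14
18 G 27
19 C 22
20 A 0
21 C 0
22 G 19
23 C 13
24 U 12
25 A 0
26 G 0
27 U 18
28 U 0
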