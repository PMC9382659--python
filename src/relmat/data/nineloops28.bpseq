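# nine-loop worked example on 28 vertices (residues unspecified, written as N)
1 N 0
2 N 6
3 N 0
4 N 11
5 N 0
6 N 2
7 N 0
8 N 13
9 N 24
10 N 18
11 N 4
12 N 0
13 N 8
14 N 0
15 N 20
16 N 19
17 N 0
18 N 10
19 N 16
20 N 15
21 N 28
22 N 27
23 N 0
24 N 9
25 N 0
26 N 0
27 N 22
28 N 21
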