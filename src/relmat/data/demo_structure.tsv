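# 6-loop demonstration structure matrix; contains the 3-loop pattern twice
N 6
1	2	x
1	3	x
1	4	o
1	5	o
1	6	o
2	3	n
2	4	x
2	5	o
2	6	o
3	4	x
3	5	o
3	6	o
4	5	x
4	6	x
5	6	n
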