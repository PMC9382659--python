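# 3-loop demonstration pattern matrix (two crossings over a nested pair)
N 3
1	2	x
1	3	x
2	3	n
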