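# Boolean input-output relations learned by the network, one pattern
# per column in the source table; here one pattern per line as
# "i1 i2 i3 i4 -> out".
1 0 0 0 -> 1
0 1 0 0 -> 1
1 1 0 0 -> 0
0 0 1 0 -> 1
0 0 0 1 -> 1
0 0 1 1 -> 0
1 1 1 1 -> 0
1 0 1 0 -> 1
1 1 1 0 -> 0
1 0 0 1 -> 1
0 1 1 0 -> 0
0 1 0 1 -> 1
1 1 0 1 -> 0
1 0 1 1 -> 1
0 1 1 1 -> 0
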