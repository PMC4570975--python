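#N=7 period=35
0110010
1001001
1001001
1001001
0100110
0111110
1000001
1000001
1000001
0100010
0000000
1000001
1111111
1000001
0000000
1111111
1001001
1001001
1001001
1000001
1111111
0100000
0010000
0001000
1111111
0111110
1000001
1000001
1000001
0100010
1111111
1001001
1001001
1001001
1000001
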