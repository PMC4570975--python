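#N=7 period=35
1000001
1001001
1001001
1001001
1111111
0100010
1000001
1000001
1000001
0111110
1111111
0001000
0010000
0100000
1111111
1000001
1001001
1001001
1001001
1111111
0000000
1000001
1111111
1000001
0000000
0100010
1000001
1000001
1000001
0111110
0100110
1001001
1001001
1001001
0110010
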