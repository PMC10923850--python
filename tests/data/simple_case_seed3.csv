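f1_1,f1_2,f1_3,f2_1,f2_2,f3_1,f3_2,label
0,0,0,0,0,0,0,0
0,0,0,0,0,0,1,1
0,0,0,0,0,1,0,1
0,0,0,0,0,1,1,0
0,0,0,0,1,0,0,0
0,0,0,0,1,0,1,1
0,0,0,0,1,1,0,1
0,0,0,0,1,1,1,0
0,0,0,1,0,0,0,0
0,0,0,1,0,0,1,1
0,0,0,1,0,1,0,1
0,0,0,1,0,1,1,0
0,0,0,1,1,0,0,1
0,0,0,1,1,0,1,0
0,0,0,1,1,1,0,0
0,0,0,1,1,1,1,1
0,0,1,0,0,0,0,0
0,0,1,0,0,0,1,1
0,0,1,0,0,1,0,1
0,0,1,0,0,1,1,0
0,0,1,0,1,0,0,0
0,0,1,0,1,0,1,1
0,0,1,0,1,1,0,1
0,0,1,0,1,1,1,0
0,0,1,1,0,0,0,0
0,0,1,1,0,0,1,1
0,0,1,1,0,1,0,1
0,0,1,1,0,1,1,0
0,0,1,1,1,0,0,1
0,0,1,1,1,0,1,0
0,0,1,1,1,1,0,0
0,0,1,1,1,1,1,1
0,1,0,0,0,0,0,0
0,1,0,0,0,0,1,1
0,1,0,0,0,1,0,1
0,1,0,0,0,1,1,0
0,1,0,0,1,0,0,0
0,1,0,0,1,0,1,1
0,1,0,0,1,1,0,1
0,1,0,0,1,1,1,0
0,1,0,1,0,0,0,0
0,1,0,1,0,0,1,1
0,1,0,1,0,1,0,1
0,1,0,1,0,1,1,0
0,1,0,1,1,0,0,1
0,1,0,1,1,0,1,0
0,1,0,1,1,1,0,0
0,1,0,1,1,1,1,1
0,1,1,0,0,0,0,0
0,1,1,0,0,0,1,1
0,1,1,0,0,1,0,1
0,1,1,0,0,1,1,0
0,1,1,0,1,0,0,0
0,1,1,0,1,0,1,1
0,1,1,0,1,1,0,1
0,1,1,0,1,1,1,0
0,1,1,1,0,0,0,0
0,1,1,1,0,0,1,1
0,1,1,1,0,1,0,1
0,1,1,1,0,1,1,0
0,1,1,1,1,0,0,1
0,1,1,1,1,0,1,0
0,1,1,1,1,1,0,0
0,1,1,1,1,1,1,1
1,0,0,0,0,0,0,0
1,0,0,0,0,0,1,1
1,0,0,0,0,1,0,1
1,0,0,0,0,1,1,0
1,0,0,0,1,0,0,0
1,0,0,0,1,0,1,1
1,0,0,0,1,1,0,1
1,0,0,0,1,1,1,0
1,0,0,1,0,0,0,0
1,0,0,1,0,0,1,1
1,0,0,1,0,1,0,1
1,0,0,1,0,1,1,0
1,0,0,1,1,0,0,1
1,0,0,1,1,0,1,0
1,0,0,1,1,1,0,0
1,0,0,1,1,1,1,1
1,0,1,0,0,0,0,0
1,0,1,0,0,0,1,0
1,0,1,0,0,1,0,0
1,0,1,0,0,1,1,0
1,0,1,0,1,0,0,0
1,0,1,0,1,0,1,0
1,0,1,0,1,1,0,0
1,0,1,0,1,1,1,0
1,0,1,1,0,0,0,0
1,0,1,1,0,0,1,0
1,0,1,1,0,1,0,0
1,0,1,1,0,1,1,0
1,0,1,1,1,0,0,0
1,0,1,1,1,0,1,1
1,0,1,1,1,1,0,1
1,0,1,1,1,1,1,0
1,1,0,0,0,0,0,0
1,1,0,0,0,0,1,1
1,1,0,0,0,1,0,1
1,1,0,0,0,1,1,0
1,1,0,0,1,0,0,0
1,1,0,0,1,0,1,1
1,1,0,0,1,1,0,1
1,1,0,0,1,1,1,0
1,1,0,1,0,0,0,0
1,1,0,1,0,0,1,1
1,1,0,1,0,1,0,1
1,1,0,1,0,1,1,0
1,1,0,1,1,0,0,1
1,1,0,1,1,0,1,0
1,1,0,1,1,1,0,0
1,1,0,1,1,1,1,1
1,1,1,0,0,0,0,0
1,1,1,0,0,0,1,0
1,1,1,0,0,1,0,0
1,1,1,0,0,1,1,0
1,1,1,0,1,0,0,0
1,1,1,0,1,0,1,0
1,1,1,0,1,1,0,0
1,1,1,0,1,1,1,0
1,1,1,1,0,0,0,0
1,1,1,1,0,0,1,0
1,1,1,1,0,1,0,0
1,1,1,1,0,1,1,0
1,1,1,1,1,0,0,0
1,1,1,1,1,0,1,1
1,1,1,1,1,1,0,1
1,1,1,1,1,1,1,0
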