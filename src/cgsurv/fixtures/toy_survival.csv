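time,status,pi
1,1,8
3,0,7
5,0,6
4,1,5
7,0,4
8,1,3
10,0,2
13,1,1
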