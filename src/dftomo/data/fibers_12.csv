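fiber,x_mm,y_mm,z_mm
1,15,30,25
2,20,35,15
3,15,20,15
4,20,25,20
5,25,30,20
6,30,35,25
7,20,15,25
8,25,20,15
9,30,25,25
10,35,30,15
11,30,15,15
12,35,20,25
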