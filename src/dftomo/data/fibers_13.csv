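fiber,x_mm,y_mm,z_mm
1,25,15,7
2,35,20,15
3,15,20,17
4,20,10,19
5,30,15,21
6,20,25,19
7,30,40,19
8,15,15,17
9,20,20,17
10,15,35,15
11,20,40,15
12,35,30,7
13,20,30,7
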