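set,1a,1b,2a,2b,3a,3b,4a,4b,5a,5b,6a,6b,ALL
B,3.9,0.0,1.5,3.7,3.4,1.8,3.2,3.1,3.7,3.5,12.7,7.5,1.8
C,10.0,10.8,12.4,15.5,6.9,6.4,10.2,7.6,15.0,14.6,14.1,8.2,5.7
D,17.2,11.2,15.8,15.4,6.6,8.8,3.2,4.1,2.8,1.9,12.3,12.1,5.2
E,1.1,1.6,17.7,18.8,1.8,4.4,7.9,25.0,1.7,1.7,9.1,8.4,4.4
BC,1.9,0.0,1.9,3.1,2.3,2.0,5.2,5.2,4.5,5.9,12.3,5.7,2.3
BD,3.4,0.0,1.5,2.4,2.2,1.1,2.2,1.4,1.4,0.0,12.8,7.0,1.6
BE,2.1,0.0,1.1,0.0,1.5,1.1,0.0,11.4,1.4,0.9,11.7,10.1,2.1
CD,8.6,2.7,8.3,6.3,1.8,4.8,5.4,5.5,2.5,2.0,14.0,8.5,3.1
CE,1.6,1.1,1.1,0.0,1.5,4.9,2.6,14.9,2.8,1.8,12.5,10.5,2.5
DE,1.1,0.0,1.1,0.0,1.1,4.0,2.5,11.4,1.4,0.8,5.8,6.4,1.2
BCD,2.6,0.0,1.2,1.5,1.5,1.5,4.2,1.0,1.7,1.2,12.0,5.7,1.5
BCE,2.8,0.0,0.0,1.1,1.1,1.8,1.2,9.2,2.5,1.8,10.6,5.7,1.6
CDE,1.1,0.0,0.0,0.0,1.5,4.6,1.6,14.3,1.3,1.8,11.1,7.3,2.1
BDE,1.8,0.0,0.0,1.1,0.0,1.1,0.0,7.1,0.0,0.0,11.7,7.0,1.4
BCDE,1.8,0.0,0.0,1.1,1.5,1.8,1.0,7.1,1.7,1.8,10.6,6.1,1.6
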