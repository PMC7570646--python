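set,V1,V2,V3,V4,V5,V6,V7,V8,V9,V10,V11,V12,V13,V14,V15,V16,V17,V18,V19,V20,ALL
B,2.0,7.8,2.4,4.6,3.1,1.9,1.5,4.1,3.3,4.5,3.7,1.4,15.8,0.0,1.4,2.9,4.3,1.1,1.1,0.0,1.1
C,2.5,5.6,3.3,2.2,11.6,5.9,5.0,7.8,4.1,12.5,7.2,17.2,15.9,3.3,13.4,13.6,22.7,13.1,11.8,4.4,3.3
D,3.9,11.1,1.9,6.5,2.5,3.2,0.0,33.8,11.3,4.1,2.7,1.9,17.2,2.9,0.0,2.5,9.1,0.0,0.0,0.0,1.5
E,6.4,9.7,7.4,23.4,3.6,1.9,2.0,3.1,10.5,14.7,1.9,31.8,5.3,16.2,1.9,3.9,16.1,4.7,4.5,11.2,5.8
BC,1.6,5.9,1.9,1.1,1.5,1.9,1.5,3.3,3.1,8.8,3.6,2.0,15.1,0.0,1.9,0.0,6.8,0.0,0.0,1.4,1.1
BD,1.7,8.4,1.9,2.9,0.0,0.0,0.0,2.4,2.9,2.6,1.4,1.4,15.4,0.0,0.0,0.0,3.0,0.0,0.0,0.0,1.1
BE,2.0,8.2,1.4,1.1,0.0,1.4,0.0,2.1,1.5,14.4,0.0,0.0,16.4,0.0,0.0,0.0,1.5,1.1,0.0,0.0,1.4
CD,1.6,6.9,1.4,1.7,2.3,6.3,1.5,12.5,1.9,6.8,0.0,5.8,15.8,0.0,0.0,0.0,13.3,1.1,1.9,0.0,1.2
CE,2.0,6.0,1.4,1.0,0.0,0.0,0.0,1.6,3.1,18.3,3.0,6.2,11.4,4.2,1.4,3.1,16.6,1.1,0.0,0.0,2.0
DE,1.8,8.4,1.9,4.1,2.1,0.0,0.0,2.3,2.3,14.4,0.0,2.9,2.1,4.1,1.4,1.5,1.4,0.0,0.0,6.5,1.3
BCD,1.6,6.0,1.4,1.1,0.0,1.5,0.0,2.1,3.1,5.3,0.0,0.0,14.2,0.0,0.0,0.0,4.8,0.0,0.0,0.0,1.0
BCE,1.5,8.2,1.4,1.5,1.5,0.0,1.5,1.6,3.1,11.8,0.0,1.4,11.4,1.4,0.0,0.0,5.7,0.0,0.0,0.0,1.1
CDE,0.0,7.4,1.4,1.0,0.0,0.0,0.0,1.6,1.4,18.3,0.0,5.8,11.4,0.0,0.0,1.5,9.8,1.1,0.0,0.0,1.6
BDE,0.0,8.3,1.4,1.3,0.0,0.0,0.0,1.6,1.5,9.2,0.0,0.0,14.3,0.0,0.0,0.0,1.5,0.0,0.0,0.0,1.1
BCDE,0.0,9.3,1.4,1.3,0.0,0.0,0.0,1.6,1.9,9.1,0.0,1.4,11.4,0.0,0.0,0.0,3.5,0.0,0.0,0.0,1.0
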