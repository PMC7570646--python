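set,V1,V2,V3,V4,V5,V6,V7,V8,V9,V10,V11,V12,V13,V14,V15,V16,V17,V18,V19,V20,ALL
B,99.1,94.8,98.4,98.3,98.7,99.1,99.6,97.7,98.3,98.0,98.4,99.6,92.6,100.0,99.6,99.1,97.3,99.6,99.6,100.0,98.4
C,98.2,94.8,98.0,97.9,92.3,97.4,97.3,94.9,95.7,91.2,94.4,88.0,85.3,97.1,87.3,88.9,75.2,94.7,93.5,98.4,93.1
D,96.9,93.1,99.2,96.9,98.3,98.7,100.0,76.2,93.1,97.6,99.2,99.2,91.1,98.2,100.0,98.3,94.6,100.0,100.0,100.0,96.7
E,97.4,95.3,95.9,88.8,97.9,99.1,99.6,97.7,94.4,93.6,99.2,81.0,96.5,94.9,99.2,98.3,92.3,97.3,97.7,94.8,95.5
BC,99.6,96.6,99.2,99.7,99.6,99.1,99.6,98.6,98.7,96.0,98.8,99.2,91.1,100.0,99.2,100.0,94.1,100.0,100.0,99.6,98.4
BD,99.1,95.7,99.2,99.0,100.0,100.0,100.0,98.6,99.1,99.2,99.6,99.6,93.8,100.0,100.0,100.0,99.1,100.0,100.0,100.0,99.1
BE,99.1,96.1,99.6,99.7,100.0,99.6,100.0,99.1,99.6,95.6,100.0,100.0,91.9,100.0,100.0,100.0,99.5,99.6,100.0,100.0,99.0
CD,99.6,97.0,99.6,99.3,98.7,97.4,99.6,92.1,99.1,97.2,100.0,97.1,93.0,100.0,100.0,100.0,88.3,99.6,99.2,100.0,97.9
CE,99.1,97.0,99.6,99.7,100.0,100.0,100.0,99.5,98.7,94.0,98.8,97.1,94.2,98.5,99.6,98.7,90.5,99.6,100.0,100.0,98.3
DE,99.1,96.1,99.2,98.6,99.1,100.0,100.0,99.1,98.7,95.6,100.0,99.2,98.8,98.5,99.6,99.6,99.5,100.0,100.0,97.2,98.9
BCD,99.6,97.4,99.6,99.7,100.0,99.6,100.0,99.1,98.7,98.0,100.0,100.0,94.6,100.0,100.0,100.0,95.9,100.0,100.0,100.0,99.1
BCE,99.6,96.6,99.6,99.3,99.6,100.0,99.6,99.5,98.7,96.0,100.0,99.6,94.6,99.6,100.0,100.0,96.4,100.0,100.0,100.0,98.9
CDE,100.0,97.0,99.6,99.7,100.0,100.0,100.0,99.5,99.6,94.0,100.0,97.9,94.6,100.0,100.0,99.6,93.7,99.6,100.0,100.0,98.7
BDE,100.0,97.0,99.6,99.7,100.0,100.0,100.0,99.5,99.6,97.2,100.0,100.0,94.6,100.0,100.0,100.0,99.5,100.0,100.0,100.0,99.3
BCDE,100.0,96.1,99.6,99.7,100.0,100.0,100.0,99.5,99.1,96.8,100.0,99.6,94.6,100.0,100.0,100.0,96.8,100.0,100.0,100.0,99.1
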