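set,1a,1b,2a,2b,3a,3b,4a,4b,5a,5b,6a,6b,ALL
B,96.9,100.0,99.5,98.5,99.0,99.3,99.1,98.6,97.9,98.2,96.0,97.6,98.4
C,90.8,91.8,95.7,96.7,94.9,92.4,95.3,93.6,87.0,88.2,94.9,97.1,93.1
D,95.2,97.2,95.5,94.2,96.6,95.1,98.4,97.6,97.9,99.3,96.5,96.0,96.7
E,99.7,99.5,95.5,95.5,99.3,97.6,96.0,79.8,99.3,99.3,91.7,92.3,95.5
BC,99.2,100.0,99.2,99.5,99.3,99.0,98.4,98.1,97.3,97.5,96.0,97.9,98.4
BD,98.2,100.0,99.5,99.2,99.5,99.8,99.3,99.5,99.5,100.0,96.3,97.9,99.1
BE,99.0,100.0,99.7,100.0,99.5,99.8,100.0,96.5,99.5,99.8,96.3,97.1,99.0
CD,96.4,99.2,97.5,98.2,99.3,98.3,97.9,97.9,98.6,99.3,95.2,96.8,97.9
CE,99.5,99.7,99.7,100.0,99.5,97.3,98.8,94.1,98.9,99.5,95.2,96.5,98.3
DE,99.7,100.0,99.7,100.0,99.8,98.0,99.1,96.2,99.5,99.8,97.6,97.1,98.9
BCD,99.0,100.0,99.7,99.7,99.5,99.5,98.6,99.8,99.3,99.5,96.5,97.9,99.1
BCE,98.7,100.0,100.0,99.7,99.8,99.3,99.5,97.2,98.9,99.5,96.5,97.9,98.9
CDE,99.7,100.0,100.0,100.0,99.5,98.0,99.3,96.0,99.5,99.5,95.7,97.3,98.7
BDE,99.2,100.0,100.0,99.7,100.0,99.8,100.0,98.4,100.0,100.0,96.5,97.9,99.3
BCDE,99.2,100.0,100.0,99.7,99.5,99.3,99.8,98.1,99.3,99.5,96.5,97.9,99.1
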