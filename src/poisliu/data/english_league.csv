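Y,X1,X2,X3,X4,X5
30,72,0,33,52,93
26,62,0,26,60,86
23,71,4,39,41,78
22,54,0,42,36,76
23,68,3,44,33,75
18,78,2,29,25,69
17,72,2,44,18,61
12,59,2,48,-7,46
12,52,3,67,-12,46
12,80,0,51,-8,45
12,78,5,64,-17,45
12,72,1,63,-15,44
11,70,2,56,-15,44
12,77,0,63,-13,41
12,56,0,70,-25,41
11,65,2,55,-16,40
11,84,5,68,-28,40
9,67,5,80,-43,34
5,77,1,53,-26,28
6,78,4,69,-40,24
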