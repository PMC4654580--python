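case,BG,HL
1,+(k),-
2,-,-
3,-,-
4,-,-
5,-,-
6,-,NE
7,-,-
8,-,-
9,-,-
10,-,-
11,-,NE
12,+(k),-
13,+(l),-
14,-,+(k)
15,-,NE
16,-,-
17,-,+(k)
18,+(l),+(l)
19,NE,-
20,-,-
21,+(l),NE
22,-,-
23,+(k),-
24,-,NE
25,NE,NE
26,-,-
27,-,-
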