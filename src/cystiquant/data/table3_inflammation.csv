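group,grade,<200,200-1000,>1000
NHIC,0,36,1,0
NHIC,1,0,1,0
NHIC,2,0,0,1
HIC,0,4,7,0
HIC,1,0,16,7
HIC,2,0,6,14
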