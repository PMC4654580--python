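feature,printed_p
Sex,0.0776
Age at biopsy,0.0054
Age at onset,0.0020
OSSI,0.9376
OSPI,0.5734
Urination frequency,0.4894
Max bladder capacity,0.0064
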