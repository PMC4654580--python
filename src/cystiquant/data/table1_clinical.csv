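feature,level,NHIC,HIC
Sex,Male,12,3
Sex,Female,27,24
Age at biopsy,<=40,11,2
Age at biopsy,41-60,7,1
Age at biopsy,>=61,21,24
Age at onset,<=40,12,2
Age at onset,41-60,13,5
Age at onset,>=61,14,20
OSSI,0-7,3,5
OSSI,8-14,25,11
OSSI,>=15,11,10
OSPI,0-7,7,4
OSPI,8-14,24,15
OSPI,>=15,8,7
Urination frequency,0-10,13,5
Urination frequency,11-20,19,17
Urination frequency,>=21,7,4
Max bladder capacity,<=400,3,8
Max bladder capacity,401-800,29,17
Max bladder capacity,>800,7,1
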