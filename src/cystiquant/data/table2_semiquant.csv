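feature,level,NHIC,HIC-BG,HIC-HL
Subepithelial inflammation,0,37,8,3
Subepithelial inflammation,1,1,11,12
Subepithelial inflammation,2,1,8,12
Lymphoid aggregate/follicle,absent,38,19,11
Lymphoid aggregate/follicle,present,1,8,16
Plasma cell-rich area,absent,38,17,15
Plasma cell-rich area,present,1,10,12
Neutrophilic infiltration,absent,38,20,15
Neutrophilic infiltration,present,1,7,12
Eosinophilic infiltration,absent,37,12,6
Eosinophilic infiltration,present,2,15,21
Full-thickness epithelium,present,38,16,12
Full-thickness epithelium,absent,1,11,15
Epithelial denudation/loss,0,33,15,5
Epithelial denudation/loss,1,5,7,6
Epithelial denudation/loss,2,1,5,16
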