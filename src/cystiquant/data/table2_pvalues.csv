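feature,comparison,printed_p
Subepithelial inflammation,NHIC vs HIC-BG,<0.0001
Subepithelial inflammation,NHIC vs HIC-HL,<0.0001
Subepithelial inflammation,HIC-BG vs HIC-HL,0.0975
Lymphoid aggregate/follicle,NHIC vs HIC-BG,0.0025
Lymphoid aggregate/follicle,NHIC vs HIC-HL,<0.0001
Lymphoid aggregate/follicle,HIC-BG vs HIC-HL,0.0542
Plasma cell-rich area,NHIC vs HIC-BG,0.0003
Plasma cell-rich area,NHIC vs HIC-HL,<0.0001
Plasma cell-rich area,HIC-BG vs HIC-HL,0.7822
Neutrophilic infiltration,NHIC vs HIC-BG,0.0064
Neutrophilic infiltration,NHIC vs HIC-HL,<0.0001
Neutrophilic infiltration,HIC-BG vs HIC-HL,0.2542
Eosinophilic infiltration,NHIC vs HIC-BG,0.0064
Eosinophilic infiltration,NHIC vs HIC-HL,<0.0001
Eosinophilic infiltration,HIC-BG vs HIC-HL,0.1480
Full-thickness epithelium,NHIC vs HIC-BG,<0.0001
Full-thickness epithelium,NHIC vs HIC-HL,<0.0001
Full-thickness epithelium,HIC-BG vs HIC-HL,0.4142
Epithelial denudation/loss,NHIC vs HIC-BG,<0.0001
Epithelial denudation/loss,NHIC vs HIC-HL,<0.0001
Epithelial denudation/loss,HIC-BG vs HIC-HL,0.0010
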