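gene,weight
ANXA5,-1.09
DLG2,1.32
ZNF264,0.55
DUSP6,0.75
CPEB4,0.59
LCK,-0.84
STAT1,-0.58
RNF4,0.65
IRF4,0.52
STAT2,0.58
HGF,0.51
ERBB3,0.55
NF1,0.47
FRAP1,-0.77
MMD,0.92
HMMR,0.52
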