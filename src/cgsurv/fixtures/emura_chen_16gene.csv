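gene,weight
MMP16,0.51
ZNF264,0.51
HGF,0.50
HCK,-0.49
NF1,0.47
ERBB3,0.46
NR2F6,0.57
AXL,0.77
CDC23,0.51
DLG2,0.92
IGF2,-0.34
RBBP6,0.54
COX11,0.51
DUSP6,0.40
ENG,-0.37
IHPK1,-0.41
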