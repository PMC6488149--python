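# 19-gene breast-cancer predisposition panel
ATM
BRCA1
BRCA2
BRIP1
CDH1
CHEK2
MLH1
MSH2
MSH6
NBN
PALB2
PMS2
PTEN
RAD51C
RAD51D
STK11
TP53
MUTYH
BARD1
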