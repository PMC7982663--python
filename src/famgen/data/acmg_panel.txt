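# ACMG secondary-findings gene panel (59 genes)
ACTA2
ACTC1
APC
APOB
ATP7B
BMPR1A
BRCA1
BRCA2
CACNA1S
COL3A1
DSC2
DSG2
DSP
FBN1
GLA
KCNH2
KCNQ1
LDLR
LMNA
MEN1
MLH1
MSH2
MSH6
MUTYH
MYBPC3
MYH11
MYH7
MYL2
MYL3
NF2
OTC
PCSK9
PKP2
PMS2
PRKAG2
PTEN
RB1
RET
RYR1
RYR2
SCN5A
SDHAF2
SDHB
SDHC
SDHD
SMAD3
SMAD4
STK11
TGFBR1
TGFBR2
TMEM43
TNNI3
TNNT2
TP53
TPM1
TSC1
TSC2
VHL
WT1
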