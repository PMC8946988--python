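AFF3
APCDD1
ASIC2
BMP6
C4orf19
C4orf3
CACNB4
CDH6
COL27A1
CYFIP2
ERG
ESR1
GFRA2
GUCY1A2
HAND1
ISM1
ISOC1
KIAA1217
LDHB
LONRF2
LPIN1
MAST4
MKX
NPY1R
NRXN3
NTM
PDE1C
PDE4B
PDE4D
PDGFD
PGR
PLCB1
PLEKHA7
PRKAG2
PRR15
PTGER4
RAP1GAP2
RETREG1
RNF152
RPS6KA2
SHANK2
SLC47A1
SLCO5A1
SNCAIP
SOX5
SVEP1
SYBU
TGFA
TMEM178B
TMOD1
TPD52L1
TSHZ2
WNT16
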