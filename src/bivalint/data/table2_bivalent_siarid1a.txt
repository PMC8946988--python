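AFF3
ANK3
C17orf51
CDH6
CELF2
CHRM3
COL27A1
CYFIP2
DEPDC1B
DLGAP4
EIF4E3
ELOVL7
FAM131B
FMN1
FOXQ1
GJB2
LONRF2
MAD2L2
MOCS1
NR3C2
NTM
PDE1C
PDE4B
PGR
PLAGL1
PLEKHA7
RAP1GAP2
RETREG1
RNF220
RPL38
RPS6KA2
SHANK2
STOX2
TMEM178B
TSHZ2
VDR
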