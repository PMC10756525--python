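gene	frequency_score
VEGFA	11
CCND1	9
SHOC2	8
ZNF264	8
AGO1	7
BCL2	7
E2F1	7
GK5	7
HMGA2	7
KMT2D	7
MKNK2	7
SIRT1	7
TGFBR2	7
YOD1	7
ACOT9	6
APOL6	6
DICER1	6
EP300	6
EPHA4	6
FZD6	6
GATA6	6
HMGB1	6
IFNLR1	6
IGF1R	6
KLHL15	6
MCL1	6
MFSD8	6
MYC	6
NFIB	6
PDPK1	6
PLAGL2	6
RPRD2	6
SCD	6
SMC1A	6
SOD2	6
TNFRSF10B	6
TUBB	6
WASL	6
ZBTB37	6
AHCYL2	5
AKT1	5
AKT2	5
ALDH9A1	5
AMD1	5
ARIH1	5
ATM	5
ATXN1	5
BCL2L11	5
BTG2	5
CAPN15	5
CARM1	5
CBX6	5
CEBPB	5
CPEB3	5
CRCP	5
CREB1	5
CSDE1	5
DDX21	5
DDX6	5
DNMT1	5
DSTYK	5
DYNC1LI2	5
EIF4G2	5
ETNK1	5
FAM3C	5
FOXK1	5
FOXO3	5
FUT10	5
GLO1	5
HMGA1	5
KIF2C	5
KLF4	5
LDLR	5
LMNB2	5
LNPK	5
MAPK1	5
MDM2	5
MTMR9	5
NACC2	5
NHLRC3	5
NR2C2	5
NUDT3	5
ORAI2	5
PBX2	5
PDE12	5
PDZD8	5
PHACTR2	5
PLEKHA1	5
PLPP3	5
PMAIP1	5
POLR1B	5
PPP6R3	5
PTEN	5
PURA	5
RAB21	5
RANGAP1	5
REEP3	5
RORA	5
RPL24	5
RRM2	5
RUNDC1	5
SEC24A	5
SFT2D2	5
SIK1	5
SLC1A5	5
SMAD7	5
SOCS1	5
SOCS5	5
SOCS7	5
SP1	5
SZRD1	5
TGFBR3	5
TMOD3	5
TNPO1	5
TNRC6A	5
TRAPPC2	5
TUBB2A	5
TWF1	5
UBE3C	5
UBXN2B	5
ULK1	5
WNK3	5
YY1	5
ZADH2	5
ZBTB4	5
ZCCHC3	5
ZNF417	5
ZNF443	5
ADCYAP1	-2
API5	-2
ARHGEF39	-2
BSDC1	-2
C18orf25	-2
C4orf26	-2
CEBPG	-2
CREB5	-2
CSGALNACT1	-2
CSRNP3	-2
DKK3	-2
ERBIN	-2
ESCO1	-2
FAM9C	-2
FER	-2
FRK	-2
GSR	-2
GUCD1	-2
HNRNPA3	-2
HNRNPL	-2
IGSF3	-2
KCTD11	-2
KCTD16	-2
LIN54	-2
LRRC8A	-2
MAPK8	-2
MRPL58	-2
MTRNR2L6	-2
NADSYN1	-2
NDNF	-2
NDUFB5	-2
NRIP1	-2
ONECUT3	-2
P2RY1	-2
PDE8A	-2
PGK1	-2
PGM3	-2
PSAT1	-2
RAET1E	-2
REEP1	-2
RNF219	-2
RNF41	-2
RPS17	-2
SCAMP1	-2
SEL1L3	-2
SEMA6A	-2
SLAMF1	-2
SNAP25	-2
SPTY2D1	-2
SYNPO	-2
TBC1D15	-2
TBXA2R	-2
TM4SF20	-2
TMEM170B	-2
UBASH3B	-2
UCHL3	-2
UVRAG	-2
VPS52	-2
VTA1	-2
YWHAG	-2
ZNF223	-2
ZNF286B	-2
CLASP1	-3
CRIPT	-3
CSNK1G3	-3
DGAT1	-3
EI24	-3
FOXP1	-3
LPP	-3
MKL2	-3
MYO10	-3
SPIN4	-4
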