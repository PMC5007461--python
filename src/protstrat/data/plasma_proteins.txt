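# Curated stand-in list of ~200 classical high-abundance plasma proteins
# (gene symbols): albumin, immunoglobulin chains, complement components,
# coagulation factors, apolipoproteins, protease inhibitors and other
# acute-phase reactants. Used by preprocess.remove_plasma_proteins before
# PCA of matrices that mix tumour-derived material with cell lines.
ALB
A1BG
A2M
AFM
AGT
AHSG
AMBP
APCS
APOA1
APOA2
APOA4
APOA5
APOB
APOC1
APOC2
APOC3
APOC4
APOD
APOE
APOF
APOH
APOL1
APOM
AZGP1
B2M
BCHE
C1QA
C1QB
C1QC
C1R
C1RL
C1S
C2
C3
C4A
C4B
C4BPA
C4BPB
C5
C6
C7
C8A
C8B
C8G
C9
CD5L
CETP
CFB
CFD
CFH
CFHR1
CFHR2
CFHR3
CFHR4
CFHR5
CFI
CFP
CLU
CP
CPB2
CPN1
CPN2
CRP
ECM1
EFEMP1
F10
F11
F12
F13A1
F13B
F2
F5
F7
F9
FBLN1
FCN2
FCN3
FETUB
FGA
FGB
FGG
FGL1
FN1
GC
GPLD1
GPX3
GSN
HABP2
HBA1
HBA2
HBB
HGFAC
HP
HPR
HPX
HRG
IGFALS
IGHA1
IGHA2
IGHD
IGHE
IGHG1
IGHG2
IGHG3
IGHG4
IGHM
IGKC
IGLC1
IGLC2
IGLC3
IGLC6
IGLC7
IGLL1
IGLL5
ITIH1
ITIH2
ITIH3
ITIH4
JCHAIN
KLKB1
KNG1
KRT1
LBP
LCAT
LGALS3BP
LPA
LRG1
LUM
MASP1
MASP2
MBL2
ORM1
ORM2
PCYOX1
PF4
PGLYRP2
PLG
PLTP
PON1
PON3
PPBP
PRG4
PROC
PROS1
PROZ
PTGDS
QSOX1
RBP4
SAA1
SAA2
SAA4
SERPINA1
SERPINA3
SERPINA4
SERPINA5
SERPINA6
SERPINA7
SERPINA10
SERPINC1
SERPIND1
SERPINF1
SERPINF2
SERPING1
SHBG
TF
TFRC
THBS1
TTR
VTN
VWF
ANGPTL3
ANGPTL6
APOB48R
ATRN
BTD
C8orf4
CA1
CA2
CD14
CNDP1
COLEC10
COLEC11
CRTAC1
CST3
DBH
F13A
FCGBP
FERMT3
FHR1
GP1BA
GP5
HPSE
IGFBP3
IGFBP4
IGFBP5
ITGA2B
ITGB3
KLK3
KRT10
KRT2
KRT9
LYZ
MMRN1
MPO
MST1
ORM
PARVB
PEPD
PI16
PLA2G7
PRDX2
S100A8
S100A9
SELENOP
SERPINB1
TLN1
TPM4
TSKU
VCL
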