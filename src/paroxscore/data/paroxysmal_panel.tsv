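gene	phenotypes
SCN1A	FHM,Sz
SCN2A	EAx,Sz
SCN4A	HOKPP,HYPP,PP
SCN9A	EPS
SCN10A	EPS
SCN11A	EPS
KCNA1	EAx
KCNJ2	Afib,ATS,PP
KCNJ18	PP
CACNA1A	EAx,FHM,Sz
CACNA1S	HOKPP,MH,PP
RYR2	CVS,VA
SLC1A3	EAx
TRPA1	EPS
ATP1A2	AHC,FBM,FHM
ATP1A3	AHC,Sz
CHAMP1	CVS,Sz
GFAP	CVS
PRRT2	EKD,FICPC,Sz
CLCN1	MC
HMBS	AIP
PDHA1	EW
POLG	EAx,CVS
PNKD	PNKD
TRAP1	EPS
MEFV	FMF
TNFRSF1A	FPF
SLC2A1	EAx,FHM,Sz
TUBB3	CVS
OTC	HYPERAMMONEMIA
POGZ	CVS
PPM1D	CVS
CDK8	CVS
CNR1	CVS
OPRM1	CVS
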