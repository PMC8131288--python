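# NMR identifier -> force-field atom name translations.
# Columns (tab separated): residues  identifier  amber_targets  charmm_targets
#   residues : comma-separated 3-letter amino-acid / nucleotide codes, or the
#              group tokens "protein" (all 20 amino acids) / "nucleic"
#              (G, A, U, C, DG, DA, DT, DC)
#   targets  : comma-separated real atom names, in subscript order
# Users may extend this file (or pass their own) to support other force
# fields or non-standard residues.
protein	H	H	HN
ALA	MB	HB1,HB2,HB3	HB1,HB2,HB3
THR	MG	HG1,HG2,HG3	HG1,HG2,HG3
ILE	MG	HG21,HG22,HG23	HG21,HG22,HG23
ILE	HG12	HG11	HG11
ILE	HG13	HG12	HG12
ILE	MD	HD1,HD2,HD3	HD1,HD2,HD3
ILE	CD1	CD	CD
ILE	HD11	HD1	HD1
ILE	HD12	HD2	HD2
ILE	HD13	HD3	HD3
GLY	HA2	HA1	HA1
GLY	HA3	HA2	HA2
SER,THR,CYS	HG	HG	HG1
LYS,ASN,SER,ASP,GLU,PRO,GLN,ARG,MET,TRP,TYR,PHE,HIS,LEU	HB2	HB1	HB1
LYS,ASN,SER,ASP,GLU,PRO,GLN,ARG,MET,TRP,TYR,PHE,HIS,LEU	HB3	HB2	HB2
LYS,ASN,SER,ASP,GLU,PRO,GLN,ARG,MET,VAL	HG2	HG1	HG1
LYS,ASN,SER,ASP,GLU,PRO,GLN,ARG,MET,VAL	HG3	HG2	HG2
LYS,ASN,SER,ASP,GLU,PRO,GLN,ARG,MET	HD2	HD1	HD1
LYS,ASN,SER,ASP,GLU,PRO,GLN,ARG,MET	HD3	HD2	HD2
LYS,ASN,SER,ASP,GLU,PRO,GLN,ARG,MET	HE2	HE1	HE1
LYS,ASN,SER,ASP,GLU,PRO,GLN,ARG,MET	HE3	HE2	HE2
MET	ME	HE1,HE2,HE3	HE1,HE2,HE3
LYS	QZ	HZ1,HZ2,HZ3	HZ1,HZ2,HZ3
ARG	QH1	HH11,HH12	HH11,HH12
ARG	QH2	HH21,HH22	HH21,HH22
LEU	MD1	HD11,HD12,HD13	HD11,HD12,HD13
LEU	MD2	HD21,HD22,HD23	HD21,HD22,HD23
TYR,PHE	QD	HD1,HD2	HD1,HD2
TYR,PHE	QE	HE1,HE2	HE1,HE2
nucleic	HO2'	HO'2	HO'2
nucleic	H5'	H5'1	H5'1
nucleic	H5''	H5'2	H5'2
nucleic	H2'	H2'1	H2'1
nucleic	H2''	H2'2	H2'2
DT	M7	H71,H72,H73	H71,H72,H73
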