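"""Published pseudo-atom / naming translation table, transcribed literally.

Kept independent of the package's data file so the table-driven tests
compare implementation output against a second transcription.
Each entry: (residues, NMR identifier, amber targets, charmm targets).
"""

PROTEIN = ("ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER "
           "THR TRP TYR VAL").split()
NUCLEIC = "G A U C DG DA DT DC".split()
HB_SHIFT = "LYS ASN SER ASP GLU PRO GLN ARG MET TRP TYR PHE HIS LEU".split()
HG_SHIFT = "LYS ASN SER ASP GLU PRO GLN ARG MET VAL".split()
HDE_SHIFT = "LYS ASN SER ASP GLU PRO GLN ARG MET".split()

TABLE1 = [
    (PROTEIN, "H", ["H"], ["HN"]),
    (["ALA"], "MB", ["HB1", "HB2", "HB3"], ["HB1", "HB2", "HB3"]),
    (["THR"], "MG", ["HG1", "HG2", "HG3"], ["HG1", "HG2", "HG3"]),
    (["ILE"], "MG", ["HG21", "HG22", "HG23"], ["HG21", "HG22", "HG23"]),
    (["ILE"], "HG12", ["HG11"], ["HG11"]),
    (["ILE"], "HG13", ["HG12"], ["HG12"]),
    (["ILE"], "MD", ["HD1", "HD2", "HD3"], ["HD1", "HD2", "HD3"]),
    (["ILE"], "CD1", ["CD"], ["CD"]),
    (["ILE"], "HD11", ["HD1"], ["HD1"]),
    (["ILE"], "HD12", ["HD2"], ["HD2"]),
    (["ILE"], "HD13", ["HD3"], ["HD3"]),
    (["GLY"], "HA2", ["HA1"], ["HA1"]),
    (["GLY"], "HA3", ["HA2"], ["HA2"]),
    (["SER", "THR", "CYS"], "HG", ["HG"], ["HG1"]),
    (HB_SHIFT, "HB2", ["HB1"], ["HB1"]),
    (HB_SHIFT, "HB3", ["HB2"], ["HB2"]),
    (HG_SHIFT, "HG2", ["HG1"], ["HG1"]),
    (HG_SHIFT, "HG3", ["HG2"], ["HG2"]),
    (HDE_SHIFT, "HD2", ["HD1"], ["HD1"]),
    (HDE_SHIFT, "HD3", ["HD2"], ["HD2"]),
    (HDE_SHIFT, "HE2", ["HE1"], ["HE1"]),
    (HDE_SHIFT, "HE3", ["HE2"], ["HE2"]),
    (["MET"], "ME", ["HE1", "HE2", "HE3"], ["HE1", "HE2", "HE3"]),
    (["LYS"], "QZ", ["HZ1", "HZ2", "HZ3"], ["HZ1", "HZ2", "HZ3"]),
    (["ARG"], "QH1", ["HH11", "HH12"], ["HH11", "HH12"]),
    (["ARG"], "QH2", ["HH21", "HH22"], ["HH21", "HH22"]),
    (["LEU"], "MD1", ["HD11", "HD12", "HD13"], ["HD11", "HD12", "HD13"]),
    (["LEU"], "MD2", ["HD21", "HD22", "HD23"], ["HD21", "HD22", "HD23"]),
    (["TYR", "PHE"], "QD", ["HD1", "HD2"], ["HD1", "HD2"]),
    (["TYR", "PHE"], "QE", ["HE1", "HE2"], ["HE1", "HE2"]),
    (NUCLEIC, "HO2'", ["HO'2"], ["HO'2"]),
    (NUCLEIC, "H5'", ["H5'1"], ["H5'1"]),
    (NUCLEIC, "H5''", ["H5'2"], ["H5'2"]),
    (NUCLEIC, "H2'", ["H2'1"], ["H2'1"]),
    (NUCLEIC, "H2''", ["H2'2"], ["H2'2"]),
    (["DT"], "M7", ["H71", "H72", "H73"], ["H71", "H72", "H73"]),
]
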