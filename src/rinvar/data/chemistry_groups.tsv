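# Interaction-group assignment of standard amino-acid heavy atoms.
# Columns: aa <TAB> group <TAB> comma-separated atom names.
# Groups: hydrophobic, donor, acceptor, cationic, anionic, ring1, ring2.
# Backbone amide N (donor; absent for PRO) and carbonyl O (acceptor) are listed
# explicitly so the table is self-contained.  Ring rows are ordered cycles.
# Hydrophobic rule: side-chain carbons of CH3-/-CH2-/-CH< groups not bonded to
# N or O, plus all aromatic ring carbons (sp2 rule).
ALA	hydrophobic	CB
ALA	donor	N
ALA	acceptor	O
ARG	hydrophobic	CB,CG
ARG	donor	N,NE,NH1,NH2
ARG	acceptor	O
ARG	cationic	NE,CZ,NH1,NH2
ASN	hydrophobic	CB
ASN	donor	N,ND2
ASN	acceptor	O,OD1
ASP	hydrophobic	CB
ASP	donor	N
ASP	acceptor	O,OD1,OD2
ASP	anionic	OD1,OD2
CYS	hydrophobic	CB
CYS	donor	N,SG
CYS	acceptor	O,SG
GLN	hydrophobic	CB,CG
GLN	donor	N,NE2
GLN	acceptor	O,OE1
GLU	hydrophobic	CB,CG
GLU	donor	N
GLU	acceptor	O,OE1,OE2
GLU	anionic	OE1,OE2
GLY	donor	N
GLY	acceptor	O
HIS	hydrophobic	CB,CG,CD2,CE1
HIS	donor	N,ND1,NE2
HIS	acceptor	O,ND1,NE2
HIS	ring1	CG,ND1,CE1,NE2,CD2
ILE	hydrophobic	CB,CG1,CG2,CD1
ILE	donor	N
ILE	acceptor	O
LEU	hydrophobic	CB,CG,CD1,CD2
LEU	donor	N
LEU	acceptor	O
LYS	hydrophobic	CB,CG,CD
LYS	donor	N,NZ
LYS	acceptor	O
LYS	cationic	NZ
MET	hydrophobic	CB,CG,CE
MET	donor	N
MET	acceptor	O,SD
PHE	hydrophobic	CB,CG,CD1,CD2,CE1,CE2,CZ
PHE	donor	N
PHE	acceptor	O
PHE	ring1	CG,CD1,CE1,CZ,CE2,CD2
PRO	hydrophobic	CB,CG,CD
PRO	acceptor	O
SER	donor	N,OG
SER	acceptor	O,OG
THR	hydrophobic	CG2
THR	donor	N,OG1
THR	acceptor	O,OG1
TRP	hydrophobic	CB,CG,CD1,CD2,CE2,CE3,CZ2,CZ3,CH2
TRP	donor	N,NE1
TRP	acceptor	O
TRP	ring1	CG,CD1,NE1,CE2,CD2
TRP	ring2	CD2,CE2,CZ2,CH2,CZ3,CE3
TYR	hydrophobic	CB,CG,CD1,CD2,CE1,CE2,CZ
TYR	donor	N,OH
TYR	acceptor	O,OH
TYR	ring1	CG,CD1,CE1,CZ,CE2,CD2
VAL	hydrophobic	CB,CG1,CG2
VAL	donor	N
VAL	acceptor	O
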