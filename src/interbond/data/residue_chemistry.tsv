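# Side-chain chemistry of the 20 canonical amino acids at physiological pH.
# Columns: residue  role  atom  detail
#   role=charge        atom='.'  detail = formal charge (+1/-1)
#   role=charged_atom  atom = side-chain N/O carrying the formal charge
#   role=donor         atom = heavy atom, detail = number of polar hydrogens
#   role=acceptor      atom = heavy atom, detail = comma-separated antecedents
#   role=reach         atom='.'  detail = Cbeta -> farthest polar/charged
#                      side-chain atom in extended conformation, angstroms
# Backbone chemistry (amide N donor except PRO, carbonyl O/OXT acceptor with
# antecedent C) is implied for every residue and added in code.
residue	role	atom	detail
ARG	charge	.	+1
HIS	charge	.	+1
LYS	charge	.	+1
ASP	charge	.	-1
GLU	charge	.	-1
ARG	charged_atom	NE	.
ARG	charged_atom	NH1	.
ARG	charged_atom	NH2	.
LYS	charged_atom	NZ	.
HIS	charged_atom	ND1	.
HIS	charged_atom	NE2	.
ASP	charged_atom	OD1	.
ASP	charged_atom	OD2	.
GLU	charged_atom	OE1	.
GLU	charged_atom	OE2	.
ARG	donor	NE	1
ARG	donor	NH1	2
ARG	donor	NH2	2
ASN	donor	ND2	2
CYS	donor	SG	1
GLN	donor	NE2	2
HIS	donor	ND1	1
HIS	donor	NE2	1
LYS	donor	NZ	3
SER	donor	OG	1
THR	donor	OG1	1
TRP	donor	NE1	1
TYR	donor	OH	1
ASN	acceptor	OD1	CG
ASP	acceptor	OD1	CG
ASP	acceptor	OD2	CG
CYS	acceptor	SG	CB
GLN	acceptor	OE1	CD
GLU	acceptor	OE1	CD
GLU	acceptor	OE2	CD
MET	acceptor	SD	CG,CE
SER	acceptor	OG	CB
THR	acceptor	OG1	CB
TYR	acceptor	OH	CZ
ALA	reach	.	0.0
ARG	reach	.	6.4
ASN	reach	.	2.6
ASP	reach	.	2.6
CYS	reach	.	1.8
GLN	reach	.	3.9
GLU	reach	.	3.9
GLY	reach	.	0.0
HIS	reach	.	4.0
ILE	reach	.	0.0
LEU	reach	.	0.0
LYS	reach	.	5.2
MET	reach	.	3.2
PHE	reach	.	0.0
PRO	reach	.	0.0
SER	reach	.	1.4
THR	reach	.	1.4
TRP	reach	.	4.9
TYR	reach	.	5.6
VAL	reach	.	0.0
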