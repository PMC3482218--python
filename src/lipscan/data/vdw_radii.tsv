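residue_name	atom_name	element	radius
ALA	N	N	1.65
ALA	CA	C	1.87
ALA	C	C	1.76
ALA	O	O	1.40
ALA	OXT	O	1.40
ALA	CB	C	1.87
ARG	N	N	1.65
ARG	CA	C	1.87
ARG	C	C	1.76
ARG	O	O	1.40
ARG	OXT	O	1.40
ARG	CB	C	1.87
ARG	CG	C	1.87
ARG	CD	C	1.87
ARG	NE	N	1.65
ARG	CZ	C	1.76
ARG	NH1	N	1.65
ARG	NH2	N	1.65
ASN	N	N	1.65
ASN	CA	C	1.87
ASN	C	C	1.76
ASN	O	O	1.40
ASN	OXT	O	1.40
ASN	CB	C	1.87
ASN	CG	C	1.76
ASN	OD1	O	1.40
ASN	ND2	N	1.65
ASP	N	N	1.65
ASP	CA	C	1.87
ASP	C	C	1.76
ASP	O	O	1.40
ASP	OXT	O	1.40
ASP	CB	C	1.87
ASP	CG	C	1.76
ASP	OD1	O	1.40
ASP	OD2	O	1.40
CYS	N	N	1.65
CYS	CA	C	1.87
CYS	C	C	1.76
CYS	O	O	1.40
CYS	OXT	O	1.40
CYS	CB	C	1.87
CYS	SG	S	1.85
GLN	N	N	1.65
GLN	CA	C	1.87
GLN	C	C	1.76
GLN	O	O	1.40
GLN	OXT	O	1.40
GLN	CB	C	1.87
GLN	CG	C	1.87
GLN	CD	C	1.76
GLN	OE1	O	1.40
GLN	NE2	N	1.65
GLU	N	N	1.65
GLU	CA	C	1.87
GLU	C	C	1.76
GLU	O	O	1.40
GLU	OXT	O	1.40
GLU	CB	C	1.87
GLU	CG	C	1.87
GLU	CD	C	1.76
GLU	OE1	O	1.40
GLU	OE2	O	1.40
GLY	N	N	1.65
GLY	CA	C	1.87
GLY	C	C	1.76
GLY	O	O	1.40
GLY	OXT	O	1.40
HIS	N	N	1.65
HIS	CA	C	1.87
HIS	C	C	1.76
HIS	O	O	1.40
HIS	OXT	O	1.40
HIS	CB	C	1.87
HIS	CG	C	1.76
HIS	ND1	N	1.65
HIS	CD2	C	1.76
HIS	CE1	C	1.76
HIS	NE2	N	1.65
ILE	N	N	1.65
ILE	CA	C	1.87
ILE	C	C	1.76
ILE	O	O	1.40
ILE	OXT	O	1.40
ILE	CB	C	1.87
ILE	CG1	C	1.87
ILE	CG2	C	1.87
ILE	CD1	C	1.87
LEU	N	N	1.65
LEU	CA	C	1.87
LEU	C	C	1.76
LEU	O	O	1.40
LEU	OXT	O	1.40
LEU	CB	C	1.87
LEU	CG	C	1.87
LEU	CD1	C	1.87
LEU	CD2	C	1.87
LYS	N	N	1.65
LYS	CA	C	1.87
LYS	C	C	1.76
LYS	O	O	1.40
LYS	OXT	O	1.40
LYS	CB	C	1.87
LYS	CG	C	1.87
LYS	CD	C	1.87
LYS	CE	C	1.87
LYS	NZ	N	1.65
MET	N	N	1.65
MET	CA	C	1.87
MET	C	C	1.76
MET	O	O	1.40
MET	OXT	O	1.40
MET	CB	C	1.87
MET	CG	C	1.87
MET	SD	S	1.85
MET	CE	C	1.87
PHE	N	N	1.65
PHE	CA	C	1.87
PHE	C	C	1.76
PHE	O	O	1.40
PHE	OXT	O	1.40
PHE	CB	C	1.87
PHE	CG	C	1.76
PHE	CD1	C	1.76
PHE	CD2	C	1.76
PHE	CE1	C	1.76
PHE	CE2	C	1.76
PHE	CZ	C	1.76
PRO	N	N	1.65
PRO	CA	C	1.87
PRO	C	C	1.76
PRO	O	O	1.40
PRO	OXT	O	1.40
PRO	CB	C	1.87
PRO	CG	C	1.87
PRO	CD	C	1.87
SER	N	N	1.65
SER	CA	C	1.87
SER	C	C	1.76
SER	O	O	1.40
SER	OXT	O	1.40
SER	CB	C	1.87
SER	OG	O	1.40
THR	N	N	1.65
THR	CA	C	1.87
THR	C	C	1.76
THR	O	O	1.40
THR	OXT	O	1.40
THR	CB	C	1.87
THR	OG1	O	1.40
THR	CG2	C	1.87
TRP	N	N	1.65
TRP	CA	C	1.87
TRP	C	C	1.76
TRP	O	O	1.40
TRP	OXT	O	1.40
TRP	CB	C	1.87
TRP	CG	C	1.76
TRP	CD1	C	1.76
TRP	CD2	C	1.76
TRP	NE1	N	1.65
TRP	CE2	C	1.76
TRP	CE3	C	1.76
TRP	CZ2	C	1.76
TRP	CZ3	C	1.76
TRP	CH2	C	1.76
TYR	N	N	1.65
TYR	CA	C	1.87
TYR	C	C	1.76
TYR	O	O	1.40
TYR	OXT	O	1.40
TYR	CB	C	1.87
TYR	CG	C	1.76
TYR	CD1	C	1.76
TYR	CD2	C	1.76
TYR	CE1	C	1.76
TYR	CE2	C	1.76
TYR	CZ	C	1.76
TYR	OH	O	1.40
VAL	N	N	1.65
VAL	CA	C	1.87
VAL	C	C	1.76
VAL	O	O	1.40
VAL	OXT	O	1.40
VAL	CB	C	1.87
VAL	CG1	C	1.87
VAL	CG2	C	1.87
ALA	SC	C	2.20
ARG	SC	N	2.20
ASN	SC	N	2.20
ASP	SC	N	2.20
CYS	SC	C	2.20
GLN	SC	N	2.20
GLU	SC	N	2.20
HIS	SC	N	2.20
ILE	SC	C	2.20
LEU	SC	C	2.20
LYS	SC	N	2.20
MET	SC	C	2.20
PHE	SC	C	2.20
PRO	SC	C	2.20
SER	SC	N	2.20
THR	SC	N	2.20
TRP	SC	C	2.20
TYR	SC	N	2.20
VAL	SC	C	2.20
LAT	CA	C	1.87
*	*	C	1.87
*	*	N	1.65
*	*	O	1.40
*	*	S	1.85
*	*	P	1.90
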