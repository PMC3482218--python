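residue_name	atom_name	group_type	volume
ALA	N	N3H1	15.7
ALA	CA	C4H1	14.4
ALA	C	C3H0	9.7
ALA	O	O1H0	15.9
ALA	OXT	O1H0	15.9
ALA	CB	C4H3	36.7
ARG	N	N3H1	15.7
ARG	CA	C4H1	14.4
ARG	C	C3H0	9.7
ARG	O	O1H0	15.9
ARG	OXT	O1H0	15.9
ARG	CB	C4H2	24.3
ARG	CG	C4H2	24.3
ARG	CD	C4H2	24.3
ARG	NE	N3H1	15.7
ARG	CZ	C3H0	9.7
ARG	NH1	N3H2	22.7
ARG	NH2	N3H2	22.7
ASN	N	N3H1	15.7
ASN	CA	C4H1	14.4
ASN	C	C3H0	9.7
ASN	O	O1H0	15.9
ASN	OXT	O1H0	15.9
ASN	CB	C4H2	24.3
ASN	CG	C3H0	9.7
ASN	OD1	O1H0	15.9
ASN	ND2	N3H2	22.7
ASP	N	N3H1	15.7
ASP	CA	C4H1	14.4
ASP	C	C3H0	9.7
ASP	O	O1H0	15.9
ASP	OXT	O1H0	15.9
ASP	CB	C4H2	24.3
ASP	CG	C3H0	9.7
ASP	OD1	O1H0	15.9
ASP	OD2	O1H0	15.9
CYS	N	N3H1	15.7
CYS	CA	C4H1	14.4
CYS	C	C3H0	9.7
CYS	O	O1H0	15.9
CYS	OXT	O1H0	15.9
CYS	CB	C4H2	24.3
CYS	SG	S2H1	36.7
GLN	N	N3H1	15.7
GLN	CA	C4H1	14.4
GLN	C	C3H0	9.7
GLN	O	O1H0	15.9
GLN	OXT	O1H0	15.9
GLN	CB	C4H2	24.3
GLN	CG	C4H2	24.3
GLN	CD	C3H0	9.7
GLN	OE1	O1H0	15.9
GLN	NE2	N3H2	22.7
GLU	N	N3H1	15.7
GLU	CA	C4H1	14.4
GLU	C	C3H0	9.7
GLU	O	O1H0	15.9
GLU	OXT	O1H0	15.9
GLU	CB	C4H2	24.3
GLU	CG	C4H2	24.3
GLU	CD	C3H0	9.7
GLU	OE1	O1H0	15.9
GLU	OE2	O1H0	15.9
GLY	N	N3H1	15.7
GLY	CA	C4H2	24.3
GLY	C	C3H0	9.7
GLY	O	O1H0	15.9
GLY	OXT	O1H0	15.9
HIS	N	N3H1	15.7
HIS	CA	C4H1	14.4
HIS	C	C3H0	9.7
HIS	O	O1H0	15.9
HIS	OXT	O1H0	15.9
HIS	CB	C4H2	24.3
HIS	CG	C3H0	9.7
HIS	ND1	N3H1	15.7
HIS	CD2	C3H1	21.3
HIS	CE1	C3H1	21.3
HIS	NE2	N3H1	15.7
ILE	N	N3H1	15.7
ILE	CA	C4H1	14.4
ILE	C	C3H0	9.7
ILE	O	O1H0	15.9
ILE	OXT	O1H0	15.9
ILE	CB	C4H1	14.4
ILE	CG1	C4H2	24.3
ILE	CG2	C4H3	36.7
ILE	CD1	C4H3	36.7
LEU	N	N3H1	15.7
LEU	CA	C4H1	14.4
LEU	C	C3H0	9.7
LEU	O	O1H0	15.9
LEU	OXT	O1H0	15.9
LEU	CB	C4H2	24.3
LEU	CG	C4H1	14.4
LEU	CD1	C4H3	36.7
LEU	CD2	C4H3	36.7
LYS	N	N3H1	15.7
LYS	CA	C4H1	14.4
LYS	C	C3H0	9.7
LYS	O	O1H0	15.9
LYS	OXT	O1H0	15.9
LYS	CB	C4H2	24.3
LYS	CG	C4H2	24.3
LYS	CD	C4H2	24.3
LYS	CE	C4H2	24.3
LYS	NZ	N4H3	21.4
MET	N	N3H1	15.7
MET	CA	C4H1	14.4
MET	C	C3H0	9.7
MET	O	O1H0	15.9
MET	OXT	O1H0	15.9
MET	CB	C4H2	24.3
MET	CG	C4H2	24.3
MET	SD	S2H0	29.2
MET	CE	C4H3	36.7
PHE	N	N3H1	15.7
PHE	CA	C4H1	14.4
PHE	C	C3H0	9.7
PHE	O	O1H0	15.9
PHE	OXT	O1H0	15.9
PHE	CB	C4H2	24.3
PHE	CG	C3H0	9.7
PHE	CD1	C3H1	21.3
PHE	CD2	C3H1	21.3
PHE	CE1	C3H1	21.3
PHE	CE2	C3H1	21.3
PHE	CZ	C3H1	21.3
PRO	N	N3H0	8.7
PRO	CA	C4H1	14.4
PRO	C	C3H0	9.7
PRO	O	O1H0	15.9
PRO	OXT	O1H0	15.9
PRO	CB	C4H2	24.3
PRO	CG	C4H2	24.3
PRO	CD	C4H2	24.3
SER	N	N3H1	15.7
SER	CA	C4H1	14.4
SER	C	C3H0	9.7
SER	O	O1H0	15.9
SER	OXT	O1H0	15.9
SER	CB	C4H2	24.3
SER	OG	O2H1	18.0
THR	N	N3H1	15.7
THR	CA	C4H1	14.4
THR	C	C3H0	9.7
THR	O	O1H0	15.9
THR	OXT	O1H0	15.9
THR	CB	C4H1	14.4
THR	OG1	O2H1	18.0
THR	CG2	C4H3	36.7
TRP	N	N3H1	15.7
TRP	CA	C4H1	14.4
TRP	C	C3H0	9.7
TRP	O	O1H0	15.9
TRP	OXT	O1H0	15.9
TRP	CB	C4H2	24.3
TRP	CG	C3H0	9.7
TRP	CD1	C3H1	21.3
TRP	CD2	C3H0	9.7
TRP	NE1	N3H1	15.7
TRP	CE2	C3H0	9.7
TRP	CE3	C3H1	21.3
TRP	CZ2	C3H1	21.3
TRP	CZ3	C3H1	21.3
TRP	CH2	C3H1	21.3
TYR	N	N3H1	15.7
TYR	CA	C4H1	14.4
TYR	C	C3H0	9.7
TYR	O	O1H0	15.9
TYR	OXT	O1H0	15.9
TYR	CB	C4H2	24.3
TYR	CG	C3H0	9.7
TYR	CD1	C3H1	21.3
TYR	CD2	C3H1	21.3
TYR	CE1	C3H1	21.3
TYR	CE2	C3H1	21.3
TYR	CZ	C3H0	9.7
TYR	OH	O2H1	18.0
VAL	N	N3H1	15.7
VAL	CA	C4H1	14.4
VAL	C	C3H0	9.7
VAL	O	O1H0	15.9
VAL	OXT	O1H0	15.9
VAL	CB	C4H1	14.4
VAL	CG1	C4H3	36.7
VAL	CG2	C4H3	36.7
ALA	SC	SYN	36.7
ARG	SC	SYN	55.0
ASN	SC	SYN	45.0
ASP	SC	SYN	45.0
CYS	SC	SYN	36.7
GLN	SC	SYN	55.0
GLU	SC	SYN	55.0
HIS	SC	SYN	55.0
ILE	SC	SYN	45.0
LEU	SC	SYN	45.0
LYS	SC	SYN	55.0
MET	SC	SYN	45.0
PHE	SC	SYN	55.0
PRO	SC	SYN	36.7
SER	SC	SYN	36.7
THR	SC	SYN	36.7
TRP	SC	SYN	65.0
TYR	SC	SYN	65.0
VAL	SC	SYN	36.7
LAT	CA	SYN	20.0
*	C	ELEM	20.0
*	N	ELEM	16.0
*	O	ELEM	16.0
*	S	ELEM	30.0
*	P	ELEM	25.0
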