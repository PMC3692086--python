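# Compact backbone-independent rotamer library.
# Columns: resname	chi1	chi2	chi3	chi4	probability
# Blank chi columns mean the residue has fewer chi angles.
SER	-60				0.45
SER	60				0.30
SER	180				0.25
CYS	-60				0.50
CYS	180				0.30
CYS	60				0.20
THR	60				0.49
THR	-60				0.43
THR	180				0.08
VAL	180				0.60
VAL	-60				0.30
VAL	60				0.10
ILE	-60	170			0.45
ILE	180	170			0.20
ILE	-60	-60			0.20
ILE	60	170			0.15
LEU	-60	175			0.55
LEU	180	65			0.30
LEU	180	175			0.10
LEU	-60	65			0.05
MET	-60	180	75		0.25
MET	-60	180	180		0.20
MET	-60	-60	-70		0.20
MET	180	180	75		0.20
MET	180	180	180		0.15
PHE	-60	90			0.45
PHE	180	80			0.35
PHE	60	90			0.20
TYR	-60	90			0.45
TYR	180	80			0.35
TYR	60	90			0.20
HIS	-60	-75			0.35
HIS	180	75			0.30
HIS	-60	75			0.20
HIS	60	-75			0.15
TRP	-60	95			0.40
TRP	180	-105			0.35
TRP	60	-90			0.25
ASP	-60	-15			0.50
ASP	180	15			0.30
ASP	60	-15			0.20
ASN	-60	-20			0.45
ASN	180	30			0.30
ASN	60	-20			0.25
GLU	-60	180	-10		0.40
GLU	180	180	10		0.30
GLU	-60	-60	-10		0.30
GLN	-60	180	-20		0.40
GLN	180	180	20		0.30
GLN	-60	-60	-40		0.30
LYS	-60	180	180	180	0.40
LYS	180	180	180	180	0.35
LYS	-60	-60	180	180	0.25
ARG	-60	180	180	180	0.35
ARG	180	180	180	180	0.30
ARG	-60	-60	180	180	0.20
ARG	-60	180	180	-85	0.15
PRO	25.4	-35.1			0.55
PRO	-25.4	35.1			0.45
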