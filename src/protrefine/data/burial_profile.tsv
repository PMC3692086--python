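# Side-chain burial intervals: 5th-95th percentile (+/-2 margin)
# of C-beta neighbor counts around the side-chain centroid over a
# synthetic ideal-geometry corpus.  Columns: resname exposure lo hi
ARG	exposed	0	6
ARG	intermediate	1	10
ASN	exposed	2	7
ASN	intermediate	2	10
ASP	exposed	1	7
ASP	intermediate	2	10
CYS	buried	8	12
CYS	exposed	0	6
CYS	intermediate	2	11
GLN	buried	5	9
GLN	exposed	2	6
GLN	intermediate	2	10
GLU	buried	6	10
GLU	exposed	2	6
GLU	intermediate	2	10
HIS	buried	9	13
HIS	exposed	1	6
HIS	intermediate	1	9
ILE	exposed	1	6
ILE	intermediate	3	11
LEU	buried	4	8
LEU	exposed	0	6
LEU	intermediate	3	10
LYS	exposed	0	6
LYS	intermediate	1	11
MET	exposed	0	6
MET	intermediate	1	10
PHE	exposed	0	6
PHE	intermediate	1	10
SER	buried	9	13
SER	exposed	2	6
SER	intermediate	3	10
THR	buried	9	13
THR	exposed	2	6
THR	intermediate	3	10
TRP	buried	9	13
TRP	exposed	0	6
TRP	intermediate	0	9
TYR	exposed	0	6
TYR	intermediate	1	11
VAL	exposed	0	7
VAL	intermediate	2	10
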