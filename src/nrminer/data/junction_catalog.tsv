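# Conserved intron junction positions inside the DBD, per ortholog group.
# position: 0-based amino-acid column relative to the DBD start (the first
# CI chelating cysteine); phase: codon phase 0/1/2.  Groups without a row
# (HR96a) have no intron in the DBD.  All catalogued junctions lie
# downstream of the complete CI module (columns >= 22); HR96b carries two
# introns flanking its extra exon between the P-box and D-box regions.
group	position	phase
TR	23	0
TRb	24	0
E78	25	1
HR96b	24	0
HR96b	28	0
HR96c	27	2
HR96d	31	0
NR1a	26	0
NR1b	39	2
HNF4	30	0
RXR1	29	1
RXR2	33	1
TR4	28	1
TLX	32	0
PNR	34	2
DSF	35	0
fax1	36	1
NHR236	37	0
CoupTFI	35	2
CoupTFII	38	0
ERR	39	1
NR4A	40	0
FTZF1	41	2
HR39	42	0
GCNF	43	1
2DBDa	44	0
2DBDb	45	1
2DBDg	46	2
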