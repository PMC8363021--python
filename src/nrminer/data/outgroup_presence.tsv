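# Ortholog-group presence in the molluscan/control outgroup used to root
# the gain/loss analysis.  present=1 means the group (or its unduplicated
# ancestor) is carried by non-flatworm lophotrochozoans/controls; the
# flatworm-specific paralog groups are absent by definition.
group	present
TR	1
TRb	0
E78	1
HR96a	0
HR96b	0
HR96c	0
HR96d	1
NR1a	0
NR1b	0
HNF4	1
RXR1	0
RXR2	1
TR4	1
TLX	1
PNR	1
DSF	1
fax1	1
NHR236	1
CoupTFI	1
CoupTFII	0
ERR	1
NR4A	1
FTZF1	1
HR39	1
GCNF	1
2DBDa	0
2DBDb	0
2DBDg	1
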