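# Curated ancestral NR complement of the flatworm common ancestor as
# reported in the source survey: 24 ortholog groups.  Recorded verbatim;
# note that two members (NR1b, CoupTFII) are elsewhere described as
# originating inside the flatworm tree, so a strict single-gain
# reconstruction cannot recover the full list — the pipeline reports the
# diff rather than asserting it.  "fax1" stands for the entry printed as
# dax1, consistent with the gene-loss discussion naming fax-1.
group	subfamily
TR	NR1
E78	NR1
HR96a	NR1
HR96b	NR1
HR96c	NR1
HR96d	NR1
NR1a	NR1
NR1b	NR1
HNF4	NR2
RXR2	NR2
TR4	NR2
TLX	NR2
PNR	NR2
DSF	NR2
fax1	NR2
NHR236	NR2
CoupTFI	NR2
CoupTFII	NR2
ERR	NR3
NR4A	NR4
FTZF1	NR5
HR39	NR5
GCNF	NR6
2DBDg	2DBD
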