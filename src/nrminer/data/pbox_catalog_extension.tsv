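# User-editable extension catalogue: canonical P-boxes for ortholog groups
# beyond the stated diagnostics.  These entries are package conventions for
# the synthetic survey and may be replaced with project-specific boxes.
pattern	label	level	canonical
CDGCKVFFKR	HNF4	group	True
CEGCKSFFRR	TLX	group	True
CEGCKTFFKR	PNR	group	True
CEGCKDFFKR	DSF	group	True
CEGCKEFFRR	fax1	group	True
CEGCKAFFKR	CoupTF	group	True
CEACKNFFRR	GCNF	group	True
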