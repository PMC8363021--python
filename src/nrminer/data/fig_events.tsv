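# Curated per-branch gain/loss events below the flatworm common ancestor,
# transcribed from the survey's gene gain/loss scheme and running text.
# edge: child-node label on the class-level tree (class_tree.nwk).
# Gains of groups already present (CoupTFII on the parasite stem, given the
# curated 24-member root set) replay as no-ops; the inconsistency is a
# documented feature of the source, not of the replay.
edge	event	group
Ml	loss	NR1b
Ml	loss	CoupTFII
Ml	loss	FTZF1
SmePar	loss	fax1
SmePar	loss	ERR
SmePar	loss	GCNF
SmePar	loss	HR96d
SmePar	gain	2DBDa
SmePar	gain	2DBDb
Sme	loss	E78
Sme	loss	CoupTFII
Parasites	gain	RXR1
Parasites	gain	CoupTFII
CestTrem	loss	NHR236
Cestoda	loss	DSF
Cestoda	loss	CoupTFII
Trematoda	gain	TRb
Trematoda	loss	NR1b
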