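# Diagnostic P-box catalogue (core): only diagnostics stated in the
# literature on flatworm NR complements.  Patterns of length 5-10 match as
# substrings of the 10-mer P-box window; the longest match wins.
# canonical=True entries define "typical" P-boxes; canonical=False entries
# are known boxes of divergent NRs.
pattern	label	level	canonical
ESCKG	NR5	subfamily	True
CDGCRG	NHR236	group	True
EACKA	ERR	group	True
CEGCKGFFRR	NR1	subfamily	True
CEGCKGFFKR	RXR|TR4|NR4A	group	True
CEPCKVFFKR	divergent-Monogenea	divergent	False
CEACKAFFQQ	divergent-Hymenolepididae	divergent	False
CDSCRAFFEM	divergent-Taeniidae	divergent	False
CEACKSFFKR	divergent-Diphyllobothriidea	divergent	False
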