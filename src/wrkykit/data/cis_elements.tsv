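# Example cis-element catalog (3-column TSV: element_id, IUPAC pattern, category).
# PLACE's native flat format is not parsed; convert entries to this layout
# (one element per line, tab-separated, '#' comments allowed).
WBOX	YTGACY	WRKY-binding
ABRE	ACGTG	ABA-responsive
ABRE3	GACGCGTGTC	ABA-responsive
LTRECORE	CCGAC	low temperature-responsive
LTRE1	CCGAAA	low temperature-responsive
SURECORE	GAGAC	sulfur-responsive
MYCATERD1	CATGTG	drought-responsive
AUXRE	TGTCTC	auxin-responsive
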