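# Simulated gastrointestinal digestion: pepsin + trypsin + chymotrypsin A,
# applied concurrently (one pot, union of sites, exhaustive).
#
# REVERSE-ENGINEERED fixture: these specificities were fit to reproduce the
# observed fragmentations of a five-peptide validation panel, not taken from
# textbook protease tables. Notable departures from textbook specificity:
# no cleavage after R in any observed context, K cleaved only before G,
# and an N-K bond cleaved. Do not treat this file as a canonical GI model;
# it is one configuration of the general rule engine.
ENZYME pepsin EC3.4.23.1
CLEAVE P1=FL
ENZYME trypsin EC3.4.21.4
CLEAVE P1=K NOT_BEFORE=ACDEFHIKLMNPQRSTVWY
CLEAVE P1=N NOT_BEFORE=ACDEFGHILMNPQRSTVWY
ENZYME chymotrypsin_A EC3.4.21.1
CLEAVE P1=FYMH
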