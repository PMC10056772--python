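# Validation panel: printed release metrics for the five antioxidative
# peptides. The A_E values for RQMSLLLRR (0.11) and RLQLLARF (0.13) are
# inconsistent with the printed fragment lists (which imply 0.22 and 0.25);
# they are kept verbatim here and documented, not asserted, in tests.
peptide	active_fragments	DH	A_E	W
RALGFDFRR	GF RR DF	37.50	0.33	0.50
RHTPFFKG	RH	57.14	0.13	0.17
RQMSLLLRR	RR SL	50.00	0.11	0.50
RLQLLARF	RL QL	42.86	0.13	0.17
KADSLISGAAQAVYNKF	KF	18.75	0.06	0.10
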