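# Validation panel: antioxidative-motif locations in the intact peptides.
# The two KADSLISGAAQAVYNKF rows carry the locations as printed in the
# source panel; direct indexing places GAA at 8-10 and VY at 13-14 (an
# apparent off-by-one in the source), so those rows are marked inconsistent
# and excluded from golden assertions.
peptide	motif	start	end	consistent
RALGFDFRR	LGF	3	5	yes
RHTPFFKG	RHT	1	3	yes
RQMSLLLRR	LLR	6	8	yes
RLQLLARF	LQL	2	4	yes
KADSLISGAAQAVYNKF	GAA	9	11	no
KADSLISGAAQAVYNKF	VY	14	15	no
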