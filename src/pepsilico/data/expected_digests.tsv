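# Validation panel: expected concurrent-digestion fragmentations of the
# five antioxidative peptides (fragments dash-joined; 1-based inclusive
# locations space-joined).
peptide	fragments	locations
RALGFDFRR	RAL-GF-DF-RR	1-3 4-5 6-7 8-9
RHTPFFKG	RH-TPF-F-K-G	1-2 3-5 6-6 7-7 8-8
RQMSLLLRR	RQM-SL-L-L-RR	1-3 4-5 6-6 7-7 8-9
RLQLLARF	RL-QL-L-ARF	1-2 3-4 5-5 6-8
KADSLISGAAQAVYNKF	KADSL-ISGAAQAVY-N-KF	1-5 6-14 15-15 16-17
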