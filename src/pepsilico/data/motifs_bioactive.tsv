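# Bioactive-fragment database fixture (BIOPEP-style records).
# Contains only motifs with documented activities used by the validation
# panels; extend by appending rows or supplying your own TSV.
sequence	activity	source
LGF	antioxidative	BIOPEP-UWM
RHT	antioxidative	BIOPEP-UWM
LLR	antioxidative	BIOPEP-UWM
LQL	antioxidative	BIOPEP-UWM
GAA	antioxidative	BIOPEP-UWM
VY	antioxidative	BIOPEP-UWM
GF	ACE inhibitor	BIOPEP-UWM
GF	DPP IV inhibitor	BIOPEP-UWM
DF	ACE inhibitor	BIOPEP-UWM
DF	DPP IV inhibitor	BIOPEP-UWM
RR	ACE inhibitor	BIOPEP-UWM
RR	DPP IV inhibitor	BIOPEP-UWM
RH	DPP IV inhibitor	BIOPEP-UWM
SL	ACE inhibitor	BIOPEP-UWM
SL	DPP IV inhibitor	BIOPEP-UWM
RL	ACE inhibitor	BIOPEP-UWM
RL	DPP IV inhibitor	BIOPEP-UWM
QL	ACE inhibitor	BIOPEP-UWM
QL	DPP IV inhibitor	BIOPEP-UWM
KF	ACE inhibitor	BIOPEP-UWM
KF	DPP IV inhibitor	BIOPEP-UWM
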