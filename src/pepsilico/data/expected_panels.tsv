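# Validation panel: printed physicochemical properties of the eight
# released bioactive dipeptides.
peptide	hydrophobicity	hydrophilicity	charge	pI	mw
GF	0.39	-1.25	0.00	5.88	222.26
RR	-1.76	3.00	2.00	12.01	330.40
DF	-0.05	0.25	-1.00	3.80	280.29
RH	-1.08	1.25	1.50	10.11	311.36
SL	0.14	-0.75	0.00	5.88	218.27
RL	-0.61	0.60	1.00	10.11	287.38
QL	-0.08	-0.80	0.00	5.88	259.33
KF	-0.25	0.25	1.00	9.11	293.38
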