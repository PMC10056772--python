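# Consensus-style hydrophobicity scale (peptide value = mean of residues).
# Constraint-fit fixture: values for R, H, L, S, Q, G, D, K, F were solved
# from published dipeptide panel means; the remaining residues are anchored
# to an Eisenberg-consensus-like set. User-replaceable (same two-column TSV).
residue	value
A	0.25
R	-1.76
N	-0.64
D	-0.71
C	0.04
Q	-0.70
E	-0.62
G	0.17
H	-0.40
I	0.73
L	0.54
K	-1.11
M	0.26
F	0.61
P	-0.07
S	-0.26
T	-0.18
V	0.54
W	0.37
Y	0.02
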