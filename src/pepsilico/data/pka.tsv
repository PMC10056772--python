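# Ionizable-group pKa fixture for the Henderson-Hasselbalch net-charge model.
# Constraint-fit: Nterm/Cterm/D/K/R solved so that the bisection pI
# reproduces a published 8-dipeptide panel (closed form: for one acid + one
# base the pI is the pKa midpoint); E, C, Y, H from a standard set since the
# panel does not constrain them. User-replaceable (same two-column TSV).
group	pKa
Nterm	8.21
Cterm	3.55
D	4.05
E	4.25
C	8.30
Y	10.07
H	6.04
K	10.01
R	12.01
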