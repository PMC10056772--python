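# Methods

## Scope and model

`pepsilico` models the desk half of a bioactive-peptide discovery workflow:
everything downstream of peptide identification and upstream of wet-lab
validation. External inputs are a peptide table (sequences over the 20
canonical residues, a bioactivity score in [0, 1] from a third-party
predictor, optional reported MW), parent-protein FASTA, a
bioactive-fragment database, a protease rule file, and plate-reader
absorbance tables. The package never predicts bioactivity scores or
toxicity labels; those are consumed as inputs or out of scope.

## Masses

Average residue masses (2-decimal table) plus one water (18.02 Da);
a monoisotopic table is selectable by flag but never the default, because
peptide MW tables in this field are conventionally printed as average
masses. Rounding everywhere is to two decimals with ties away from zero,
matching table conventions (1/8 → 0.13). Validation: the 22-peptide
screening fixture reproduces every reported MW within ±0.1 Da and the
8-dipeptide panel within ±0.05 Da. One known discrepancy: QL is printed as
259.33 in the source panel while every standard average-mass table gives
259.31; the originating tool's mass table is unknown, so the test tolerance
for dipeptides is ±0.05 Da rather than being "corrected".

## Digestion engine

A protease is a list of per-bond rules in P2/P1/P1′ notation. Bond *i*
(1-based, internal) joins residues *i* and *i+1*; a bond is cleaved iff
some rule matches (P1 in the rule's set, P1′ not blocked, no exception
triplet matching). Default digestion is concurrent ("one pot"): cleavage
sites are the union over enzymes and digestion is exhaustive, so fragments
are the maximal runs between cleaved bonds. Fragments carry 1-based
inclusive coordinates and are checked to tile the source exactly. A
sequential mode (enzymes applied in order to the running fragment set) is
available behind a flag; for rules that consult only P1/P1′ it provably
coincides with the concurrent result. `check_idempotent` re-digests each
released fragment and reports (never silently accepts) any further
cleavage, which can only arise from P2-dependent exceptions near new
termini.

**The shipped `gi_simulated.rules` fixture is reverse-engineered**, fit to
reproduce the observed fragmentations of a five-peptide validation panel
under a pepsin + trypsin + chymotrypsin A simulation. The observed evidence
it encodes: cleavage after L, F, M, Y and H in all observed contexts;
cleavage of K–G and N–K bonds but not K–A or K–F; and *no* cleavage after R
in any observed context (R–R, R–F, R–H, R–Q, R–L all intact). Several of
these depart from textbook specificities, and the panel exercises only a
fraction of the 400 possible P1/P1′ pairs, so the fixture's generality
beyond the panel is unknown. It should be treated as one configuration of
the general engine, not as a canonical GI model; the rule grammar
(`ENZYME` / `CLEAVE P1= NOT_BEFORE= EXCEPT=`) accepts user rule files.
The "only before G" style restrictions are expressed with `NOT_BEFORE`
complement sets to keep the grammar minimal.

## Motif statistics

Two deliberately different matching modes. Substring scanning (overlaps
included) locates motifs *within* intact peptides and feeds the occurrence
frequency `A = a/N`. Whole-fragment matching classifies *released* digest
fragments: a fragment is bioactive only if its entire sequence is a
database record — which is why a released GF dipeptide counts while a
released TPF tripeptide containing no full record does not. Matching is
case-insensitive with no wildcards.

The shipped database holds only the motifs used by the validation panels
(six antioxidative tri/di-peptides; eight ACE-/DPP-IV-inhibitory
dipeptides); it is intentionally tiny, and `W = A_E / A` is therefore
database-dependent: with a fuller database, `A` grows and `W` shrinks. The
report always carries the raw count `d` next to `A_E` so the numerator is
auditable. Two known source-data inconsistencies are documented rather than
patched: (i) the printed locations of GAA and VY in KADSLISGAAQAVYNKF are
one right of where direct indexing (and the digestion panel's own
coordinates for the same sequence) place them — the golden tests cover the
four consistent rows and separately assert the direct-indexing positions;
(ii) the printed A_E values for RQMSLLLRR (0.11) and RLQLLARF (0.13) equal
1/N although each peptide's own printed fragment list shows two released
active fragments (2/9 = 0.22, 2/8 = 0.25), suggesting they were computed
for a single unstated activity class; these two are not asserted.

## Release metrics

`DH% = 100 · (cleaved bonds)/(N−1)` — the theoretical degree of hydrolysis
implied by the simulated digestion, not a kinetic quantity. `A_E = d/N`
counts released fragments whose whole sequence carries the chosen
activity. Both are invariantly re-derivable as `(fragments − 1)/(N − 1)`
and are reported per (peptide, activity) row. `W` is reported missing (NA),
not 0, when `A = 0`, and is computed from the unrounded ratios so that
releasing every occurrence reports `W = 1.00` rather than a rounding echo.

## Physicochemical panel

Five descriptors per peptide: mean hydrophobicity, mean Hopp-Woods
hydrophilicity, formal charge (R, K +1; H +0.5; D, E −1; termini net 0),
pI, and average MW. Hopp-Woods reproduces all eight panel hydrophilicity
values exactly and is shipped verbatim.

**Hydrophobicity scale (constraint-fit).** The originating tool's scale is
not documented, but the eight dipeptide means constrain nine residues
linearly: R = −1.76, H = −0.40, L = 0.54, S = −0.26, Q = −0.70 directly,
and the pair sums G+F = 0.78, D+F = −0.10, K+F = −0.50. We anchor
F = 0.61 (Eisenberg-consensus-like) which fixes G = 0.17, D = −0.71,
K = −1.11; the eleven unconstrained residues take consensus-scale values.
All eight panel means then reproduce exactly. The scale is a two-column
TSV and user-replaceable.

**pKa set (constraint-fit).** The net charge
`Z(pH) = Σ_basic 1/(1+10^(pH−pKa)) − Σ_acidic 1/(1+10^(pKa−pH))` is
strictly decreasing in pH, so pI is the unique root, found by bisection on
[0, 14] to |Z| < 1e-4 (≈47 halvings; 200 allowed). For a peptide whose
only ionizable groups are one acid and one base, the root is exactly the
pKa midpoint — this closed form lets the panel pIs be inverted directly:
pI(GF/SL/QL) = 5.88 gives Nterm + Cterm = 11.76; pI(RL) = 10.11 gives
Nterm + R = 20.22; pI(KF) = 9.11 gives Nterm + K = 18.22; pI(RR) = 12.01
then pins Nterm = 8.21 (hence Cterm = 3.55, R = 12.01, K = 10.01), and
pI(DF) = 3.80 yields D = 4.05. E, C, Y, H (4.25, 8.30, 10.07, 6.04) come
from a standard set as the panel does not constrain them. All eight panel
pIs reproduce within ±0.01. These values are a fit to one 8-dipeptide
panel, not thermodynamic constants; the TSV is user-replaceable.

## Assay arithmetic and IC50

DPPH: `R = 1 − (As − Ac)/Ab`; colorimetric kits and ABTS share
`R = (A₀ − A₁)/A₀`. Values outside [0, 1] are returned as computed with a
warning — negative scavenging is a meaningful blank artifact. IC50 default
is a four-parameter logistic `R(c) = bottom + (top−bottom)/(1+(IC50/c)^h)`
fit by bounded least squares with the bottom fixed at 0 and the top free
(the variant used by common dose-response software is unstated, so the most
common fixed-bottom form was chosen; `fix_bottom=None` frees it). The
initial IC50 guess is the geometric mean of the tested concentrations.
Interpolation mode does log-linear interpolation at R = 0.5 and requires
bracketing. Experimental IC50 values from wet-lab fractions are not
reproduction targets; they only set the magnitude of the synthetic plates.

## Synthetic data

The peptidome generator emulates the study scale: 108 parent proteins
(uniform residue background by default; a cyanobacteria-like frequency
table by option), 230 peptides of 5–30 residues drawn as contiguous
substrings of their parents, masses recomputed with the package mass
table, and scores from Beta(2, 5) — mean 0.29 with ≈11 % of peptides
clearing the 0.5 threshold, matching the ~22/230 screening yield. The
assay generator samples the 4PL at 8 concentrations (0.05–6.4 mg/mL
around a true IC50 of 0.83 mg/mL), adds Gaussian noise (sd 0.02, the
scale of plate-reader replicate scatter), and back-converts to DPPH
absorbance triples that invert exactly. A single integer seed threads
`numpy.random.default_rng`; identical specs produce byte-identical files.

What the generators do *not* emulate: identification error, missed or
nonspecific cleavage in the upstream MS workflow, retention behaviour,
score–sequence correlation (scores are independent of composition), and
absorbance nonlinearity. Passing tests therefore demonstrate correctness
of the pipeline arithmetic under clean inputs, not robustness to real
LC-MS/MS artefacts.

## Problem sizes in the test suite

Property suites run 10,000 random digestion cases (length ≤ 12, ≤ 3 random
rules against a per-bond brute-force oracle), 1,000 random motif scans
against an all-substrings oracle, 1,000 random pI solves against a 1e-3
grid scan, and 200 seeded IC50 recovery replicates — sizes at which the
oracles are still exact and the whole suite completes in seconds.

## Known limitations

Canonical residues only (no PTMs, no B/J/O/U/X/Z); no partial or
probabilistic digestion, missed-cleavage enumeration, or enzyme kinetics;
no toxicity classification (only the descriptor panel of such tools);
no Trolox calibration or plate-layout handling; the fixtures' provenance
caveats above.
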