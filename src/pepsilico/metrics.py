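"""Quantitative release statistics of simulated digestion.

For a peptide of N residues digested into fragments:

* ``DH%`` — theoretical degree of hydrolysis: the percentage of the N-1
  peptide bonds that were cleaved.
* ``A`` — occurrence frequency of fragments with a given activity in the
  *intact* sequence (substring occurrences per residue, a/N).
* ``A_E`` — frequency of *release* of fragments with the activity by the
  chosen enzymes: d/N, where d counts released fragments whose whole
  sequence carries the activity.
* ``W = A_E / A`` — relative release frequency; undefined (reported as
  missing) when A = 0. W depends on the motif database in use and should be
  read as fixture-dependent.

Values are reported to 2 decimals, ties rounded away from zero (1/8 ->
0.13, 1/17 -> 0.06). The per-activity count d is always reported alongside
A_E so the chosen numerator is auditable.
"""

from __future__ import annotations

import pandas as pd

from .cleavage import DigestResult, EnzymeSpec, digest
from .core import Peptide, round_half_up
from .motifs import MotifDB, classify_released_fragments, occurrence_statistic_a


def degree_of_hydrolysis(digest_result: DigestResult) -> float:
    """Theoretical DH% = 100 * cleaved bonds / (N - 1), to 2 decimals."""
    n = len(digest_result.source)
    if n < 2:
        raise ValueError("degree of hydrolysis is undefined for a single residue")
    return round_half_up(100.0 * len(digest_result.cleaved_bonds) / (n - 1))


def release_frequency_ae(d: int, n: int) -> float:
    """A_E = d / N, to 2 decimals: released active fragments per residue."""
    if n < 1:
        raise ValueError("residue count must be at least 1")
    if d < 0:
        raise ValueError("released-fragment count cannot be negative")
    return round_half_up(d / n)


def relative_release_w(a_e: float, a: float) -> float:
    """W = A_E / A, to 2 decimals; raises when A = 0 (W is then undefined)."""
    if a <= 0:
        raise ValueError("W is undefined when the occurrence frequency A is 0")
    return round_half_up(a_e / a)


def metrics_report(
    peptides: list[Peptide | str],
    enzymes: list[EnzymeSpec] | tuple[EnzymeSpec, ...],
    db: MotifDB,
) -> pd.DataFrame:
    """One row per (peptide, activity): DH, d, A_E, A, W.

    W is left missing (NA) where A = 0. Deterministic given inputs.
    """
    rows = []
    for p in peptides:
        pep = p if isinstance(p, Peptide) else Peptide(id=p, sequence=p)
        result = digest(pep.sequence, enzymes)
        dh = degree_of_hydrolysis(result)
        n = len(pep.sequence)
        classified = classify_released_fragments(result, db)
        for activity in db.activities:
            d = sum(1 for c in classified if activity in c.activities)
            a_e = release_frequency_ae(d, n)
            a = occurrence_statistic_a(pep.sequence, db, activity)
            # W from the unrounded ratios, so that d released out of d
            # occurrences reports W = 1.00 rather than a rounding echo
            w = relative_release_w(d / n, a) if a > 0 else None
            rows.append(
                {
                    "peptide_id": pep.id,
                    "activity": activity,
                    "DH": dh,
                    "d": d,
                    "A_E": a_e,
                    "A": round_half_up(a),
                    "W": w,
                }
            )
    return pd.DataFrame(
        rows, columns=["peptide_id", "activity", "DH", "d", "A_E", "A", "W"]
    )
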