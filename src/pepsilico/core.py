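"""Residue alphabet, mass arithmetic, and peptide table ingestion.

Everything downstream (digestion, motif statistics, physicochemical panels)
works on validated sequences over the 20 canonical one-letter codes; this
module is the single place where raw text becomes a trusted sequence and
where molecular masses are computed.

Masses are *average* masses by default, carried to two decimals — the
precision at which peptide MW tables are conventionally printed — with a
monoisotopic table selectable by flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: Average residue (i.e. water-subtracted) masses, Da, to 2 decimals.
AVERAGE_RESIDUE_MASS: dict[str, float] = {
    "G": 57.05, "A": 71.08, "S": 87.08, "P": 97.12, "V": 99.13,
    "T": 101.10, "C": 103.14, "L": 113.16, "I": 113.16, "N": 114.10,
    "D": 115.09, "Q": 128.13, "K": 128.17, "E": 129.12, "M": 131.19,
    "H": 137.14, "F": 147.18, "R": 156.19, "Y": 163.18, "W": 186.21,
}

#: Monoisotopic residue masses, Da.
MONOISOTOPIC_RESIDUE_MASS: dict[str, float] = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

WATER_AVERAGE = 18.02
WATER_MONOISOTOPIC = 18.01056

#: Formal charge contribution per residue at neutral pH (His counted half).
FORMAL_CHARGE: dict[str, float] = {"R": 1.0, "K": 1.0, "H": 0.5, "D": -1.0, "E": -1.0}


class SequenceError(ValueError):
    """Raised when a raw string is not a valid canonical peptide sequence."""


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (the convention of printed tables:
    1/8 -> 0.13, not 0.12)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def validate_sequence(raw: str) -> str:
    """Upper-case and validate a peptide sequence.

    Raises :class:`SequenceError` naming the first offending 1-based
    position if any character is not a canonical one-letter code.
    """
    if not isinstance(raw, str) or not raw:
        raise SequenceError("empty peptide sequence")
    seq = raw.strip().upper()
    if not seq:
        raise SequenceError("empty peptide sequence")
    for i, ch in enumerate(seq, start=1):
        if ch not in AVERAGE_RESIDUE_MASS:
            raise SequenceError(
                f"non-canonical residue {ch!r} at position {i} in {seq!r}"
            )
    return seq


@dataclass
class Peptide:
    """An identified peptide: validated sequence plus external annotations.

    ``score`` is an externally supplied bioactivity likelihood in [0, 1]
    (e.g. from a neural ranker); it is consumed, never computed, here.
    """

    id: str
    sequence: str
    parent_protein: str | None = None
    score: float | None = None
    reported_mw: float | None = None

    def __post_init__(self) -> None:
        self.sequence = validate_sequence(self.sequence)
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score {self.score} outside [0, 1] for {self.id}")

    def __len__(self) -> int:
        return len(self.sequence)


def average_mass(sequence: str, monoisotopic: bool = False) -> float:
    """Molecular mass of a peptide in Da: sum of residue masses plus one water.

    Average masses by default; pass ``monoisotopic=True`` for the
    monoisotopic table.
    """
    seq = validate_sequence(sequence)
    if monoisotopic:
        return sum(MONOISOTOPIC_RESIDUE_MASS[r] for r in seq) + WATER_MONOISOTOPIC
    return sum(AVERAGE_RESIDUE_MASS[r] for r in seq) + WATER_AVERAGE


def read_peptide_table(path: str | Path) -> list[Peptide]:
    """Read a peptide TSV with header ``id sequence parent_protein score
    reported_mw`` (the last three optional per row).

    Malformed rows (bad sequence, score outside [0, 1]) are rejected with a
    warning naming the row number. Duplicate ids are deduplicated by
    suffixing, with a warning.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"id": str})
    required = {"id", "sequence"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"peptide table missing columns: {sorted(missing)}")
    if df.empty:
        warnings.warn(f"peptide table {path} has no data rows")
        return []

    peptides: list[Peptide] = []
    seen: dict[str, int] = {}
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            pid = str(row.id)
            if pid in seen:
                seen[pid] += 1
                new_id = f"{pid}__{seen[pid]}"
                warnings.warn(f"duplicate id {pid!r} at row {row_no}; renamed {new_id!r}")
                pid = new_id
            else:
                seen[pid] = 0
            score = getattr(row, "score", None)
            score = None if score is None or pd.isna(score) else float(score)
            mw = getattr(row, "reported_mw", None)
            mw = None if mw is None or pd.isna(mw) else float(mw)
            parent = getattr(row, "parent_protein", None)
            parent = None if parent is None or pd.isna(parent) else str(parent)
            peptides.append(
                Peptide(id=pid, sequence=str(row.sequence), parent_protein=parent,
                        score=score, reported_mw=mw)
            )
        except (SequenceError, ValueError) as exc:
            warnings.warn(f"rejected row {row_no}: {exc}")
    return peptides


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read protein sequences from FASTA into an ordered {name: sequence} map."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    return records


@dataclass
class MwBinSummary:
    """Proportions (%) of peptides per molecular-weight bin."""

    counts: dict[str, int]
    percent: dict[str, float]
    total: int


def mw_bin_summary(
    peptides: Iterable[Peptide | float],
    bins: tuple[float, float, float] = (500.0, 1000.0, 2000.0),
) -> MwBinSummary:
    """Bin peptide masses into [b0, b1), [b1, b2), >= b2, plus a below-range
    bin for masses under b0, and report percentages of the total.

    Accepts Peptide objects (mass recomputed from sequence) or raw masses.
    """
    b0, b1, b2 = bins
    if not (b0 < b1 < b2):
        raise ValueError("bins must be strictly increasing")
    masses = [
        average_mass(p.sequence) if isinstance(p, Peptide) else float(p)
        for p in peptides
    ]
    if not masses:
        raise ValueError("mw_bin_summary requires at least one peptide")
    labels = {
        "below": lambda m: m < b0,
        f"{b0:g}-{b1:g}": lambda m: b0 <= m < b1,
        f"{b1:g}-{b2:g}": lambda m: b1 <= m < b2,
        f">={b2:g}": lambda m: m >= b2,
    }
    counts = {lab: sum(1 for m in masses if pred(m)) for lab, pred in labels.items()}
    n = len(masses)
    percent = {lab: round_half_up(100.0 * c / n, 1) for lab, c in counts.items()}
    return MwBinSummary(counts=counts, percent=percent, total=n)
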