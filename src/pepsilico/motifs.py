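"""Bioactive-fragment database and motif scanning.

Two matching modes, deliberately distinct:

* **substring scanning** of an intact peptide (overlapping occurrences
  included) — used to locate known bioactive motifs *within* a sequence and
  to compute the occurrence frequency ``A = a / N``;
* **whole-fragment matching** of released digest fragments — a fragment is
  bioactive only if its *entire* sequence is a database record. This is why
  a released GF dipeptide can be active while a released TPF tripeptide
  containing no full record is not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import pandas as pd

from .cleavage import DigestResult
from .core import Peptide, validate_sequence
from .physchem import _data_path


@dataclass(frozen=True)
class MotifRecord:
    sequence: str
    activity: str
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", validate_sequence(self.sequence))
        if not self.activity:
            raise ValueError("motif record needs a non-empty activity label")


@dataclass
class MotifDB:
    """Bioactive-fragment records indexed by activity label."""

    records: list[MotifRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        deduped: dict[tuple[str, str], MotifRecord] = {}
        for rec in self.records:
            key = (rec.sequence, rec.activity)
            if key in deduped:
                warnings.warn(f"duplicate motif record {key}; collapsed")
            else:
                deduped[key] = rec
        self.records = list(deduped.values())
        self._by_activity: dict[str, list[MotifRecord]] = {}
        for rec in self.records:
            self._by_activity.setdefault(rec.activity, []).append(rec)

    @property
    def activities(self) -> list[str]:
        return sorted(self._by_activity)

    def motifs(self, activity: str | None = None) -> list[str]:
        """Motif sequences for one activity (or all, deduplicated)."""
        if activity is None:
            return sorted({r.sequence for r in self.records})
        return [r.sequence for r in self._by_activity.get(activity, [])]

    def activities_of(self, sequence: str) -> list[str]:
        seq = sequence.upper()
        return sorted({r.activity for r in self.records if r.sequence == seq})

    def __len__(self) -> int:
        return len(self.records)


def load_motif_db(path: str | Path) -> MotifDB:
    """Load a ``sequence activity source`` TSV into a MotifDB."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"sequence", "activity"} - set(df.columns)
    if missing:
        raise ValueError(f"motif TSV missing columns: {sorted(missing)}")
    records = [
        MotifRecord(
            sequence=str(r.sequence),
            activity=str(r.activity),
            source=str(getattr(r, "source", "")),
        )
        for r in df.itertuples(index=False)
    ]
    if not records:
        warnings.warn(f"motif TSV {path} is empty")
    return MotifDB(records=records)


@lru_cache(maxsize=1)
def default_motif_db() -> MotifDB:
    """The shipped fixture DB (antioxidative tri/di-peptide motifs plus the
    ACE- and DPP-IV-inhibitory dipeptides of the validation panel)."""
    return load_motif_db(_data_path("motifs_bioactive.tsv"))


def _seq_of(peptide: Peptide | str) -> str:
    return peptide.sequence if isinstance(peptide, Peptide) else validate_sequence(peptide)


def scan(
    peptide: Peptide | str, db: MotifDB, activity: str | None = None
) -> list[tuple[str, int, int]]:
    """Every occurrence (overlaps included) of every motif with the given
    activity, as (motif, start, end) with 1-based inclusive coordinates,
    sorted by start then motif length. Unknown activity -> empty list.
    """
    seq = _seq_of(peptide)
    motifs = sorted(set(db.motifs(activity)))
    hits: list[tuple[str, int, int]] = []
    for motif in motifs:
        m = len(motif)
        for i in range(len(seq) - m + 1):
            if seq[i : i + m] == motif:
                hits.append((motif, i + 1, i + m))
    hits.sort(key=lambda h: (h[1], h[2] - h[1]))
    return hits


def occurrence_statistic_a(
    peptide: Peptide | str, db: MotifDB, activity: str | None = None
) -> float:
    """Occurrence frequency A = a / N: motif occurrences with the activity in
    the intact sequence, per residue. Unrounded; round at report time."""
    seq = _seq_of(peptide)
    return len(scan(seq, db, activity)) / len(seq)


@dataclass
class ClassifiedFragment:
    fragment: str
    start: int
    end: int
    activities: list[str]


def classify_released_fragments(
    digest_result: DigestResult, db: MotifDB
) -> list[ClassifiedFragment]:
    """Released fragments whose whole sequence is a DB record, in release
    order, with their matched activity labels."""
    out = []
    for frag, start, end in digest_result.fragments:
        acts = db.activities_of(frag)
        if acts:
            out.append(ClassifiedFragment(frag, start, end, acts))
    return out
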