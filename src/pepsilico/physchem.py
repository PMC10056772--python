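"""Physicochemical safety panel for peptides.

Five descriptors per peptide: mean hydrophobicity (configurable scale),
mean Hopp-Woods hydrophilicity, formal charge, isoelectric point, and
average molecular weight.

The isoelectric point is the root of the Henderson-Hasselbalch net-charge
function

    Z(pH) = sum_basic 1/(1 + 10^(pH - pKa)) - sum_acidic 1/(1 + 10^(pKa - pH))

over the peptide's ionizable groups (N-terminus, C-terminus, and the side
chains of D, E, C, Y, H, K, R). Z is strictly decreasing in pH, so the root
exists and is unique; it is found by bisection on [0, 14].

The shipped hydrophobicity scale and pKa set are constraint-fit fixtures
(see the TSV headers); both are user-replaceable files in the same format.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path

import pandas as pd

from .core import Peptide, average_mass, round_half_up, validate_sequence

_POSITIVE_SIDE_CHAINS = ("H", "K", "R")
_NEGATIVE_SIDE_CHAINS = ("D", "E", "C", "Y")

_FORMAL_CONTRIBUTION = {"R": 1.0, "K": 1.0, "H": 0.5, "D": -1.0, "E": -1.0}


def _data_path(name: str) -> Path:
    return Path(str(resources.files("pepsilico").joinpath("data", name)))


def load_scale(path: str | Path) -> dict[str, float]:
    """Load a two-column ``residue value`` TSV into a residue -> value map."""
    df = pd.read_csv(path, sep="\t", comment="#")
    scale = {str(r.residue).upper(): float(r.value) for r in df.itertuples(index=False)}
    for res in scale:
        validate_sequence(res)
    return scale


@dataclass(frozen=True)
class PkaSet:
    """Ionization constants for the net-charge model."""

    n_term: float
    c_term: float
    side_chain: dict[str, float]  # keys among D, E, C, Y, H, K, R

    def __post_init__(self) -> None:
        values = [self.n_term, self.c_term, *self.side_chain.values()]
        if not all(0.0 < v < 14.0 for v in values):
            raise ValueError("all pKa values must lie in (0, 14)")
        if self.c_term >= self.n_term:
            raise ValueError("C-terminal pKa must be below the N-terminal pKa")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PkaSet":
        df = pd.read_csv(path, sep="\t", comment="#")
        vals = {str(r.group): float(r.pKa) for r in df.itertuples(index=False)}
        n = vals.pop("Nterm")
        c = vals.pop("Cterm")
        return cls(n_term=n, c_term=c, side_chain=vals)


@lru_cache(maxsize=1)
def default_pka_set() -> PkaSet:
    return PkaSet.from_tsv(_data_path("pka.tsv"))


@lru_cache(maxsize=1)
def hopp_woods_scale() -> dict[str, float]:
    return load_scale(_data_path("hopp_woods.tsv"))


@lru_cache(maxsize=1)
def default_hydrophobicity_scale() -> dict[str, float]:
    return load_scale(_data_path("hydrophobicity.tsv"))


def _mean_over_scale(sequence: str, scale: dict[str, float]) -> float:
    seq = validate_sequence(sequence)
    missing = sorted(set(seq) - set(scale))
    if missing:
        raise KeyError(f"residues missing from scale: {missing}")
    return sum(scale[r] for r in seq) / len(seq)


def hydrophilicity(sequence: str) -> float:
    """Mean Hopp-Woods hydrophilicity, to 2 decimals."""
    return round_half_up(_mean_over_scale(sequence, hopp_woods_scale()))


def hydrophobicity(sequence: str, scale: dict[str, float] | None = None) -> float:
    """Mean hydrophobicity over the given (default: shipped) scale, 2 decimals."""
    return round_half_up(
        _mean_over_scale(sequence, scale or default_hydrophobicity_scale())
    )


def formal_charge(sequence: str) -> float:
    """Formal charge: R, K +1; H +0.5; D, E -1; termini net zero."""
    seq = validate_sequence(sequence)
    return round_half_up(sum(_FORMAL_CONTRIBUTION.get(r, 0.0) for r in seq))


def charge_at_pH(sequence: str, pH: float, pka_set: PkaSet | None = None) -> float:
    """Net charge of the peptide at the given pH under the
    Henderson-Hasselbalch model."""
    if not (0.0 <= pH <= 14.0):
        raise ValueError("pH must be in [0, 14]")
    seq = validate_sequence(sequence)
    pk = pka_set or default_pka_set()
    z = 1.0 / (1.0 + 10.0 ** (pH - pk.n_term))
    z -= 1.0 / (1.0 + 10.0 ** (pk.c_term - pH))
    for r in seq:
        if r in _POSITIVE_SIDE_CHAINS:
            z += 1.0 / (1.0 + 10.0 ** (pH - pk.side_chain[r]))
        elif r in _NEGATIVE_SIDE_CHAINS:
            z -= 1.0 / (1.0 + 10.0 ** (pk.side_chain[r] - pH))
    return z


def isoelectric_point(
    sequence: str,
    pka_set: PkaSet | None = None,
    tol: float = 1e-4,
    rounded: bool = True,
) -> float:
    """Isoelectric point by bisection of the net-charge function on [0, 14].

    The charge is strictly decreasing in pH, so the zero crossing is unique.
    Iterates until |Z| < ``tol``; the value is reported to 2 decimals unless
    ``rounded=False``.
    """
    pk = pka_set or default_pka_set()
    lo, hi = 0.0, 14.0
    mid = 7.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        z = charge_at_pH(sequence, mid, pk)
        if abs(z) < tol:
            break
        if z > 0:
            lo = mid
        else:
            hi = mid
    return round_half_up(mid) if rounded else mid


@dataclass
class PropertyPanel:
    """The five-descriptor panel for one peptide."""

    peptide_id: str
    sequence: str
    hydrophobicity: float
    hydrophilicity: float
    charge: float
    pI: float
    mw: float


def property_panel(
    peptide: Peptide | str,
    scale: dict[str, float] | None = None,
    pka_set: PkaSet | None = None,
) -> PropertyPanel:
    """Assemble the full descriptor panel for one peptide."""
    if isinstance(peptide, str):
        peptide = Peptide(id=peptide, sequence=peptide)
    seq = peptide.sequence
    return PropertyPanel(
        peptide_id=peptide.id,
        sequence=seq,
        hydrophobicity=hydrophobicity(seq, scale),
        hydrophilicity=hydrophilicity(seq),
        charge=formal_charge(seq),
        pI=isoelectric_point(seq, pka_set),
        mw=round_half_up(average_mass(seq)),
    )


def panel_table(
    peptides: list[Peptide | str],
    scale: dict[str, float] | None = None,
    pka_set: PkaSet | None = None,
) -> pd.DataFrame:
    """One panel row per peptide, as a DataFrame (empty input -> empty table)."""
    cols = ["peptide_id", "sequence", "hydrophobicity", "hydrophilicity",
            "charge", "pI", "mw"]
    rows = [vars(property_panel(p, scale, pka_set)) for p in peptides]
    return pd.DataFrame(rows, columns=cols)
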