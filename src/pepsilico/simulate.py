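"""Synthetic inputs emulating the study conditions.

Two generators, both fully seeded:

* a simulated LC-MS/MS peptidome — random parent proteins and ~230
  contiguous subpeptides of 5-30 residues with Beta-distributed external
  bioactivity scores, written as FASTA + peptide TSV;
* simulated dose-response plates — 4PL responses with Gaussian noise,
  back-converted to DPPH-style absorbance triples.

`emit_fixtures` writes the machine-readable validation panels shipped with
the package (screened peptides, motif DB, expected fragmentations, metrics
and property panels) to a directory.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CANONICAL_RESIDUES, average_mass, round_half_up
from .physchem import _data_path

#: Approximate residue frequencies of a cyanobacterial proteome (optional
#: alternative to the uniform background).
CYANO_FREQUENCIES = {
    "A": 0.091, "R": 0.055, "N": 0.040, "D": 0.052, "C": 0.010,
    "Q": 0.045, "E": 0.062, "G": 0.075, "H": 0.020, "I": 0.058,
    "L": 0.104, "K": 0.045, "M": 0.021, "F": 0.040, "P": 0.047,
    "S": 0.056, "T": 0.055, "V": 0.069, "W": 0.013, "Y": 0.042,
}


@dataclass
class SyntheticPeptidomeSpec:
    """Study-scale peptidome: ~230 peptides of 5-30 residues from ~108
    parent proteins, scores Beta(2, 5) so that roughly a tenth of peptides
    clear a 0.5 bioactivity threshold."""

    n_proteins: int = 108
    protein_length_range: tuple[int, int] = (80, 400)
    n_peptides: int = 230
    peptide_length_range: tuple[int, int] = (5, 30)
    score_beta: tuple[float, float] = (2.0, 5.0)
    residue_frequencies: dict[str, float] | None = None  # None -> uniform
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1 or self.n_peptides < 1:
            raise ValueError("counts must be >= 1")
        lo, hi = self.peptide_length_range
        if lo < 2 or hi < lo:
            raise ValueError("peptide lengths must be >= 2 and ordered")
        if self.protein_length_range[0] < hi:
            raise ValueError("shortest protein must fit the longest peptide")


def simulate_peptidome(
    spec: SyntheticPeptidomeSpec,
    fasta_path: str | Path | None = None,
    tsv_path: str | Path | None = None,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Generate proteins and peptides; optionally write FASTA and TSV.

    Every peptide is a contiguous substring of its named parent; the MW
    column is recomputed from the sequence with the package mass table.
    """
    rng = np.random.default_rng(spec.seed)
    residues = np.array(list(CANONICAL_RESIDUES))
    if spec.residue_frequencies is None:
        probs = None
    else:
        probs = np.array([spec.residue_frequencies[r] for r in residues])
        probs = probs / probs.sum()

    proteins: dict[str, str] = {}
    for i in range(spec.n_proteins):
        length = int(rng.integers(*spec.protein_length_range, endpoint=True))
        seq = "".join(rng.choice(residues, size=length, p=probs))
        proteins[f"protein_{i + 1:04d}"] = seq

    names = list(proteins)
    rows = []
    for j in range(spec.n_peptides):
        parent = names[int(rng.integers(len(names)))]
        pseq = proteins[parent]
        length = int(rng.integers(*spec.peptide_length_range, endpoint=True))
        start = int(rng.integers(0, len(pseq) - length + 1))
        seq = pseq[start : start + length]
        score = float(rng.beta(*spec.score_beta))
        rows.append(
            {
                "id": f"pep_{j + 1:04d}",
                "sequence": seq,
                "parent_protein": parent,
                "score": round(score, 4),
                "reported_mw": round_half_up(average_mass(seq), 1),
            }
        )
    table = pd.DataFrame(rows)

    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            for name, seq in proteins.items():
                fh.write(f">{name}\n")
                for k in range(0, len(seq), 60):
                    fh.write(seq[k : k + 60] + "\n")
    if tsv_path is not None:
        table.to_csv(tsv_path, sep="\t", index=False)
    return proteins, table


@dataclass
class SyntheticAssaySpec:
    """Dose-response plate around the magnitude of the study's strongest
    fraction (IC50 ~0.83 mg/mL), 8 concentrations, triplicate wells."""

    true_ic50: float = 0.83
    slope: float = 1.5
    top: float = 1.0
    bottom: float = 0.0
    concentrations: tuple[float, ...] = (0.05, 0.1, 0.2, 0.4, 0.8, 1.6, 3.2, 6.4)
    replicates: int = 3
    noise_sd: float = 0.02
    blank_absorbance: float = 0.50
    control_absorbance: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        if np.any(c <= 0) or np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be positive and increasing")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.true_ic50 <= 0:
            raise ValueError("IC50 must be positive")


def simulate_assay(
    spec: SyntheticAssaySpec, csv_path: str | Path | None = None
) -> pd.DataFrame:
    """Simulate a DPPH-style plate: 4PL responses + Gaussian noise,
    expressed as absorbance triples so that the scavenging equation
    recovers exactly the noisy response."""
    from .assay import four_param_logistic

    rng = np.random.default_rng(spec.seed)
    rows = []
    for c in spec.concentrations:
        r_true = float(
            four_param_logistic(
                np.array([c]), spec.bottom, spec.top, spec.true_ic50, spec.slope
            )[0]
        )
        for rep in range(1, spec.replicates + 1):
            r_obs = r_true + float(rng.normal(0.0, spec.noise_sd))
            # invert R = 1 - (As - Ac)/Ab for the sample absorbance
            a_s = spec.control_absorbance + (1.0 - r_obs) * spec.blank_absorbance
            rows.append(
                {
                    "concentration": c,
                    "replicate": rep,
                    "assay": "DPPH",
                    "As": round(a_s, 6),
                    "Ab": spec.blank_absorbance,
                    "Ac": spec.control_absorbance,
                }
            )
    plate = pd.DataFrame(rows)
    if csv_path is not None:
        plate.to_csv(csv_path, index=False)
    return plate


_FIXTURE_FILES = (
    "peptides_screened.tsv",
    "motifs_bioactive.tsv",
    "expected_digests.tsv",
    "expected_metrics.tsv",
    "expected_panels.tsv",
    "expected_motif_scan.tsv",
    "gi_simulated.rules",
    "hopp_woods.tsv",
    "hydrophobicity.tsv",
    "pka.tsv",
)


def emit_fixtures(outdir: str | Path) -> Path:
    """Copy the shipped validation fixtures into ``outdir`` and return it."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name in _FIXTURE_FILES:
        shutil.copy(_data_path(name), out / name)
    return out
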