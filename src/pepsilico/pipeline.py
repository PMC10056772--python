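"""End-to-end orchestration: filter -> scan -> digest -> classify ->
metrics -> panel.

The pipeline consumes a peptide table whose bioactivity scores come from an
external predictor (they are never computed here), screens it at a score
threshold (default 0.5), locates bioactive motifs in the retained
sequences, simulates gastrointestinal digestion, classifies the released
fragments against the motif database, and computes release statistics and
physicochemical panels.

Runs are deterministic: identical config and inputs produce byte-identical
output tables (the run manifest records a config hash, not a timestamp).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cleavage import default_gi_enzymes, digest_batch, load_enzyme_specs
from .core import Peptide, mw_bin_summary, read_peptide_table
from .metrics import metrics_report
from .motifs import classify_released_fragments, default_motif_db, load_motif_db, scan
from .physchem import PkaSet, default_pka_set, load_scale, panel_table


@dataclass
class PipelineConfig:
    score_threshold: float = 0.5
    mw_bins: tuple[float, float, float] = (500.0, 1000.0, 2000.0)
    rule_file: str | None = None        # None -> shipped GI fixture
    motif_db_path: str | None = None    # None -> shipped fixture DB
    hydrophobicity_scale: str | None = None
    pka_file: str | None = None
    scan_activity: str | None = "antioxidative"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.score_threshold <= 1.0):
            raise ValueError("score threshold must be in [0, 1]")
        b = self.mw_bins
        if not (b[0] < b[1] < b[2]):
            raise ValueError("MW bins must be strictly increasing")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "mw_bins" in raw:
            raw["mw_bins"] = tuple(raw["mw_bins"])
        return cls(**raw)

    def digest_hash(self) -> str:
        blob = json.dumps(vars(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def score_filter(peptides: list[Peptide], threshold: float) -> list[Peptide]:
    """Retain peptides with score >= threshold, in stable input order.

    Rows without a score are skipped with a warning (the score is an
    external input; its absence is a data defect, not a zero).
    """
    kept = []
    for p in peptides:
        if p.score is None:
            warnings.warn(f"peptide {p.id} has no score; skipped by the filter")
            continue
        if p.score >= threshold:
            kept.append(p)
    return kept


@dataclass
class PipelineReport:
    config: PipelineConfig
    filtered: pd.DataFrame
    mw_summary: pd.DataFrame
    motif_hits: pd.DataFrame
    digests: pd.DataFrame
    classified: pd.DataFrame
    metrics: pd.DataFrame
    panels: pd.DataFrame
    counts: dict[str, int] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> Path:
        """Write one TSV per stage plus a JSON run manifest."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        header = (
            f"# pepsilico {__version__}  config_hash={self.config.digest_hash()}\n"
        )
        tables = {
            "filtered_peptides.tsv": self.filtered,
            "mw_summary.tsv": self.mw_summary,
            "motif_hits.tsv": self.motif_hits,
            "digests.tsv": self.digests,
            "classified_fragments.tsv": self.classified,
            "release_metrics.tsv": self.metrics,
            "property_panels.tsv": self.panels,
        }
        for name, df in tables.items():
            with open(out / name, "w") as fh:
                fh.write(header)
                df.to_csv(fh, sep="\t", index=False)
        manifest = {
            "tool": "pepsilico",
            "version": __version__,
            "config": {k: list(v) if isinstance(v, tuple) else v
                       for k, v in vars(self.config).items()},
            "config_hash": self.config.digest_hash(),
            "row_counts": self.counts,
        }
        (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
        return out


def run_pipeline(
    config: PipelineConfig, peptides: list[Peptide] | str | Path
) -> PipelineReport:
    """Execute all stages on a peptide list (or peptide-TSV path)."""
    if isinstance(peptides, (str, Path)):
        peptides = read_peptide_table(peptides)

    enzymes = (
        load_enzyme_specs(config.rule_file)
        if config.rule_file
        else list(default_gi_enzymes())
    )
    db = (
        load_motif_db(config.motif_db_path)
        if config.motif_db_path
        else default_motif_db()
    )
    scale = (
        load_scale(config.hydrophobicity_scale)
        if config.hydrophobicity_scale
        else None
    )
    pka = PkaSet.from_tsv(config.pka_file) if config.pka_file else default_pka_set()

    counts = {"input": len(peptides)}
    kept = score_filter(peptides, config.score_threshold)
    counts["filtered"] = len(kept)
    counts["rejected"] = counts["input"] - counts["filtered"]

    filtered_df = pd.DataFrame(
        [
            {
                "id": p.id,
                "sequence": p.sequence,
                "parent_protein": p.parent_protein,
                "score": p.score,
                "reported_mw": p.reported_mw,
            }
            for p in kept
        ],
        columns=["id", "sequence", "parent_protein", "score", "reported_mw"],
    )

    if kept:
        summary = mw_bin_summary(kept, config.mw_bins)
        mw_df = pd.DataFrame(
            [
                {"bin": lab, "count": summary.counts[lab], "percent": summary.percent[lab]}
                for lab in summary.counts
            ]
        )
    else:
        mw_df = pd.DataFrame(columns=["bin", "count", "percent"])

    hit_rows = []
    scanned = []
    for p in kept:
        hits = scan(p, db, config.scan_activity)
        if hits:
            scanned.append(p)
        for motif, start, end in hits:
            hit_rows.append(
                {
                    "peptide_id": p.id,
                    "motif": motif,
                    "activity": config.scan_activity or "any",
                    "start": start,
                    "end": end,
                }
            )
    motif_df = pd.DataFrame(
        hit_rows, columns=["peptide_id", "motif", "activity", "start", "end"]
    )
    counts["with_motif"] = len(scanned)

    # peptides carrying at least one motif of interest go on to digestion
    results = digest_batch([p.sequence for p in scanned], enzymes)
    digest_rows = []
    classified_rows = []
    released: list[Peptide] = []
    seen_frag: set[str] = set()
    for p, res in zip(scanned, results):
        for frag, start, end in res.fragments:
            digest_rows.append(
                {"peptide_id": p.id, "fragment": frag, "start": start, "end": end}
            )
        for c in classify_released_fragments(res, db):
            classified_rows.append(
                {
                    "peptide_id": p.id,
                    "fragment": c.fragment,
                    "start": c.start,
                    "end": c.end,
                    "activities": ";".join(c.activities),
                }
            )
            if c.fragment not in seen_frag:
                seen_frag.add(c.fragment)
                released.append(Peptide(id=c.fragment, sequence=c.fragment))
    digests_df = pd.DataFrame(
        digest_rows, columns=["peptide_id", "fragment", "start", "end"]
    )
    classified_df = pd.DataFrame(
        classified_rows, columns=["peptide_id", "fragment", "start", "end", "activities"]
    )
    counts["digested"] = len(scanned)
    counts["released_active_unique"] = len(released)

    metrics_df = metrics_report(scanned, enzymes, db)
    panels_df = panel_table(released, scale=scale, pka_set=pka)

    return PipelineReport(
        config=config,
        filtered=filtered_df,
        mw_summary=mw_df,
        motif_hits=motif_df,
        digests=digests_df,
        classified=classified_df,
        metrics=metrics_df,
        panels=panels_df,
        counts=counts,
    )
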