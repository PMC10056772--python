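"""Declarative protease-specificity engine and simulated digestion.

A protease is a set of per-bond rules in P2/P1/P1' notation (P1 is the
residue N-terminal to the scissile bond, P1' the residue C-terminal to it).
Bond ``i`` (1-based, ``1 <= i <= N-1``) joins residues ``i`` and ``i+1``.
A bond is cleaved iff some rule of some enzyme matches it and no exception
pattern of that rule suppresses the match.

The default digestion is concurrent ("one pot"): the cleavage-site set is
the union over all enzymes, and digestion is exhaustive, so the fragments
are simply the runs between consecutive cleaved bonds. A sequential mode
(enzymes applied one after another to the running fragment set) is provided
behind a flag; for context rules that only consult P1/P1' the two modes
coincide.

Rule files are line-oriented text::

    ENZYME <name> <EC>
    CLEAVE P1=<residues> [NOT_BEFORE=<residues>] [EXCEPT=<P2xP1xP1',...>]

``EXCEPT`` patterns are triplets over residues or the wildcard ``x`` that
suppress an otherwise-matching bond.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

from .core import Peptide, validate_sequence
from .physchem import _data_path

WILDCARD = "x"


@dataclass(frozen=True)
class CleavageRule:
    """One specificity rule: cleave after any residue in ``p1`` unless the
    following residue is in ``not_before`` or an exception triplet matches."""

    p1: frozenset[str]
    not_before: frozenset[str] = frozenset()
    exceptions: tuple[tuple[str, str, str], ...] = ()

    def __post_init__(self) -> None:
        if not self.p1:
            raise ValueError("rule needs a non-empty P1 set")
        for res in self.p1 | self.not_before:
            validate_sequence(res)
        for pat in self.exceptions:
            if len(pat) != 3:
                raise ValueError(f"exception pattern must be a P2/P1/P1' triplet: {pat}")
            for res in pat:
                if res != WILDCARD:
                    validate_sequence(res)

    def matches(self, p2: str | None, p1: str, p1_prime: str) -> bool:
        if p1 not in self.p1 or p1_prime in self.not_before:
            return False
        for e2, e1, e1p in self.exceptions:
            if (
                (e1 == WILDCARD or e1 == p1)
                and (e1p == WILDCARD or e1p == p1_prime)
                and (e2 == WILDCARD or (p2 is not None and e2 == p2))
            ):
                return False
        return True


@dataclass
class EnzymeSpec:
    name: str
    ec: str
    rules: list[CleavageRule]


@dataclass
class DigestResult:
    """Fragments of one peptide after exhaustive digestion.

    Fragments carry 1-based inclusive coordinates and tile the source
    exactly; ``len(fragments) == len(cleaved_bonds) + 1``.
    """

    source: str
    cleaved_bonds: frozenset[int]
    fragments: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.source)
        if any(not 1 <= b <= n - 1 for b in self.cleaved_bonds):
            raise ValueError("cleaved bond index outside [1, N-1]")
        if not self.fragments:
            self.fragments = _fragments_from_bonds(self.source, self.cleaved_bonds)
        # tiling invariant
        assert "".join(f for f, _, _ in self.fragments) == self.source
        assert self.fragments[0][1] == 1 and self.fragments[-1][2] == n
        assert len(self.fragments) == len(self.cleaved_bonds) + 1


def _fragments_from_bonds(seq: str, bonds: frozenset[int]) -> list[tuple[str, int, int]]:
    cuts = sorted(bonds)
    starts = [1] + [b + 1 for b in cuts]
    ends = cuts + [len(seq)]
    return [(seq[s - 1 : e], s, e) for s, e in zip(starts, ends)]


def load_enzyme_specs(path: str | Path) -> list[EnzymeSpec]:
    """Parse a rule file into enzyme specs; rejects malformed patterns and
    duplicate enzyme names."""
    specs: list[EnzymeSpec] = []
    current: EnzymeSpec | None = None
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if parts[0] == "ENZYME":
            if len(parts) < 3:
                raise ValueError(f"line {lineno}: ENZYME needs a name and EC number")
            name = parts[1]
            if any(s.name == name for s in specs):
                raise ValueError(f"line {lineno}: duplicate enzyme name {name!r}")
            current = EnzymeSpec(name=name, ec=parts[2], rules=[])
            specs.append(current)
        elif parts[0] == "CLEAVE":
            if current is None:
                raise ValueError(f"line {lineno}: CLEAVE before any ENZYME header")
            kv = {}
            for tok in parts[1:]:
                key, _, val = tok.partition("=")
                kv[key] = val
            if "P1" not in kv:
                raise ValueError(f"line {lineno}: CLEAVE needs P1=<residues>")
            exc: list[tuple[str, str, str]] = []
            for pat in filter(None, kv.get("EXCEPT", "").split(",")):
                if len(pat) != 3:
                    raise ValueError(f"line {lineno}: bad EXCEPT triplet {pat!r}")
                exc.append((pat[0], pat[1], pat[2]))
            current.rules.append(
                CleavageRule(
                    p1=frozenset(kv["P1"]),
                    not_before=frozenset(kv.get("NOT_BEFORE", "")),
                    exceptions=tuple(exc),
                )
            )
        else:
            raise ValueError(f"line {lineno}: unrecognized directive {parts[0]!r}")
    if not specs:
        warnings.warn(f"rule file {path} defines no enzymes")
    return specs


@lru_cache(maxsize=1)
def default_gi_enzymes() -> tuple[EnzymeSpec, ...]:
    """The shipped simulated-GI fixture (pepsin, trypsin, chymotrypsin A).

    Reverse-engineered from a five-peptide validation panel; see the rule
    file header for caveats.
    """
    return tuple(load_enzyme_specs(_data_path("gi_simulated.rules")))


def _seq_of(peptide: Peptide | str) -> str:
    return peptide.sequence if isinstance(peptide, Peptide) else validate_sequence(peptide)


def find_cleavage_sites(
    peptide: Peptide | str, enzymes: list[EnzymeSpec] | tuple[EnzymeSpec, ...]
) -> set[int]:
    """Union of cleaved bond indices over all enzymes (concurrent digestion)."""
    seq = _seq_of(peptide)
    sites: set[int] = set()
    for i in range(1, len(seq)):  # bond i joins residues i, i+1
        p2 = seq[i - 2] if i >= 2 else None
        p1, p1p = seq[i - 1], seq[i]
        if any(r.matches(p2, p1, p1p) for e in enzymes for r in e.rules):
            sites.add(i)
    return sites


def digest(
    peptide: Peptide | str,
    enzymes: list[EnzymeSpec] | tuple[EnzymeSpec, ...],
    sequential: bool = False,
) -> DigestResult:
    """Exhaustively digest one peptide.

    Concurrent (default): union of sites over enzymes, fragments between
    consecutive cleaved bonds. Sequential: enzymes applied in order, each
    digesting the fragments left by the previous one; site indices are
    mapped back to source coordinates.
    """
    seq = _seq_of(peptide)
    if not sequential:
        sites = find_cleavage_sites(seq, enzymes)
        return DigestResult(source=seq, cleaved_bonds=frozenset(sites))

    fragments: list[tuple[str, int]] = [(seq, 1)]  # (sequence, source start)
    sites: set[int] = set()
    for enzyme in enzymes:
        next_frags: list[tuple[str, int]] = []
        for frag, start in fragments:
            local = find_cleavage_sites(frag, [enzyme])
            sites.update(start - 1 + b for b in local)
            for sub, s, _e in _fragments_from_bonds(frag, frozenset(local)):
                next_frags.append((sub, start + s - 1))
        fragments = next_frags
    return DigestResult(source=seq, cleaved_bonds=frozenset(sites))


def digest_batch(
    peptides: list[Peptide | str],
    enzymes: list[EnzymeSpec] | tuple[EnzymeSpec, ...],
    sequential: bool = False,
) -> list[DigestResult]:
    """Element-wise :func:`digest`, preserving input order."""
    return [digest(p, enzymes, sequential=sequential) for p in peptides]


def check_idempotent(result: DigestResult, enzymes) -> list[str]:
    """Re-digest each released fragment; return the fragments that would be
    cleaved further (violations of exhaustive digestion), empty if none.

    Context rules are re-evaluated on the fragment, so a P2-dependent rule
    can in principle fire differently near new termini; violations are
    reported, not silently accepted.
    """
    violations = []
    for frag, _s, _e in result.fragments:
        if len(frag) >= 2 and find_cleavage_sites(frag, enzymes):
            violations.append(frag)
    return violations
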