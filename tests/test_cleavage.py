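"""Protease rule engine and simulated digestion."""

import numpy as np
import pytest

from conftest import PANEL
from pepsilico.cleavage import (
    CleavageRule,
    EnzymeSpec,
    check_idempotent,
    digest,
    digest_batch,
    find_cleavage_sites,
    load_enzyme_specs,
)
from pepsilico.core import CANONICAL_RESIDUES

TRYPSIN_CLASSIC = EnzymeSpec(
    name="trypsin_classic",
    ec="3.4.21.4",
    rules=[CleavageRule(p1=frozenset("KR"), not_before=frozenset("P"))],
)


def brute_force_sites(seq, enzymes):
    """Independent per-bond oracle: re-evaluate every rule on every bond."""
    sites = set()
    for i in range(1, len(seq)):
        p2 = seq[i - 2] if i >= 2 else None
        p1, p1p = seq[i - 1], seq[i]
        for enzyme in enzymes:
            for rule in enzyme.rules:
                if p1 not in rule.p1 or p1p in rule.not_before:
                    continue
                suppressed = False
                for e2, e1, e1p in rule.exceptions:
                    ok2 = e2 == "x" or (p2 is not None and e2 == p2)
                    ok1 = e1 == "x" or e1 == p1
                    ok1p = e1p == "x" or e1p == p1p
                    if ok2 and ok1 and ok1p:
                        suppressed = True
                        break
                if not suppressed:
                    sites.add(i)
    return sites


def random_rule_set(rng, n_enzymes=2, max_rules=2):
    enzymes = []
    residues = list(CANONICAL_RESIDUES)
    for e in range(n_enzymes):
        rules = []
        for _ in range(int(rng.integers(1, max_rules + 1))):
            p1 = frozenset(rng.choice(residues, size=int(rng.integers(1, 4)), replace=False))
            nb = frozenset(rng.choice(residues, size=int(rng.integers(0, 3)), replace=False))
            exc = ()
            if rng.random() < 0.3:
                pat = tuple(
                    "x" if rng.random() < 0.5 else str(rng.choice(residues))
                    for _ in range(3)
                )
                exc = (pat,)
            rules.append(CleavageRule(p1=p1, not_before=nb, exceptions=exc))
        enzymes.append(EnzymeSpec(name=f"e{e}", ec="0.0.0.0", rules=rules))
    return enzymes


class TestRuleFile:
    def test_fixture_defines_three_enzymes(self, gi_enzymes):
        assert [e.name for e in gi_enzymes] == ["pepsin", "trypsin", "chymotrypsin_A"]
        assert {e.ec for e in gi_enzymes} == {
            "EC3.4.23.1", "EC3.4.21.4", "EC3.4.21.1",
        }

    def test_empty_file_warns(self, tmp_path):
        path = tmp_path / "empty.rules"
        path.write_text("# nothing here\n")
        with pytest.warns(UserWarning, match="no enzymes"):
            assert load_enzyme_specs(path) == []

    def test_non_canonical_p1_rejected(self, tmp_path):
        path = tmp_path / "bad.rules"
        path.write_text("ENZYME e1 EC0\nCLEAVE P1=B\n")
        with pytest.raises(Exception):
            load_enzyme_specs(path)

    def test_duplicate_enzyme_name_rejected(self, tmp_path):
        path = tmp_path / "dup.rules"
        path.write_text("ENZYME e1 EC0\nCLEAVE P1=K\nENZYME e1 EC0\nCLEAVE P1=R\n")
        with pytest.raises(ValueError, match="duplicate enzyme"):
            load_enzyme_specs(path)

    def test_except_triplets_parse_and_suppress(self, tmp_path):
        path = tmp_path / "exc.rules"
        path.write_text("ENZYME e1 EC0\nCLEAVE P1=K EXCEPT=xKP,AKx\n")
        (enz,) = load_enzyme_specs(path)
        assert find_cleavage_sites("GKPG", [enz]) == set()  # K-P suppressed
        assert find_cleavage_sites("AKGG", [enz]) == set()  # A-K-x suppressed
        assert find_cleavage_sites("GKGG", [enz]) == {2}


class TestGiFixtureDigestion:
    @pytest.mark.parametrize(
        "seq,bonds",
        [
            ("RALGFDFRR", {3, 5, 7}),
            ("RHTPFFKG", {2, 5, 6, 7}),
            ("RQMSLLLRR", {3, 5, 6, 7}),
            ("RLQLLARF", {2, 4, 5}),
            ("KADSLISGAAQAVYNKF", {5, 14, 15}),
        ],
    )
    def test_panel_cleavage_sites(self, gi_enzymes, seq, bonds):
        assert find_cleavage_sites(seq, gi_enzymes) == bonds

    def test_panel_fragmentations_match_expectations(self, gi_enzymes, expected_digests):
        for row in expected_digests.itertuples(index=False):
            result = digest(row.peptide, gi_enzymes)
            frags = [f for f, _, _ in result.fragments]
            locs = [f"{s}-{e}" for _, s, e in result.fragments]
            assert "-".join(frags) == row.fragments, row.peptide
            assert " ".join(locs) == row.locations, row.peptide

    def test_no_match_gives_single_fragment(self):
        result = digest("AAAA", [TRYPSIN_CLASSIC])
        assert result.fragments == [("AAAA", 1, 4)]
        assert find_cleavage_sites("AAAA", [TRYPSIN_CLASSIC]) == set()

    def test_panel_digestion_is_exhaustive(self, gi_enzymes):
        """Re-digesting released fragments yields nothing further."""
        for seq in PANEL:
            assert check_idempotent(digest(seq, gi_enzymes), gi_enzymes) == []

    def test_sequential_equals_concurrent_for_p1_rules(self, gi_enzymes):
        for seq in PANEL:
            assert digest(seq, gi_enzymes, sequential=True).cleaved_bonds == digest(
                seq, gi_enzymes
            ).cleaved_bonds


class TestBatch:
    def test_preserves_order_and_determinism(self, gi_enzymes):
        results = digest_batch(PANEL + [PANEL[0]], gi_enzymes)
        assert [r.source for r in results] == PANEL + [PANEL[0]]
        assert results[0].fragments == results[-1].fragments

    def test_empty_list(self, gi_enzymes):
        assert digest_batch([], gi_enzymes) == []


class TestProperties:
    def test_tiling_and_oracle_on_random_cases(self):
        """10,000 random (peptide, rule set) cases: fragments tile the
        source exactly and the site set equals the brute-force oracle."""
        rng = np.random.default_rng(1234)
        residues = np.array(list(CANONICAL_RESIDUES))
        for _ in range(10_000):
            n = int(rng.integers(2, 13))
            seq = "".join(rng.choice(residues, size=n))
            enzymes = random_rule_set(rng)
            result = digest(seq, enzymes)
            assert "".join(f for f, _, _ in result.fragments) == seq
            assert len(result.fragments) == len(result.cleaved_bonds) + 1
            assert result.fragments[0][1] == 1 and result.fragments[-1][2] == n
            for (_, _, e1), (_, s2, _) in zip(result.fragments, result.fragments[1:]):
                assert s2 == e1 + 1
            assert result.cleaved_bonds == frozenset(brute_force_sites(seq, enzymes))

    def test_union_monotonicity(self):
        """Adding an enzyme never removes a cleavage site."""
        rng = np.random.default_rng(99)
        residues = np.array(list(CANONICAL_RESIDUES))
        for _ in range(500):
            seq = "".join(rng.choice(residues, size=int(rng.integers(2, 13))))
            base = random_rule_set(rng, n_enzymes=1)
            extra = base + random_rule_set(rng, n_enzymes=1)
            assert find_cleavage_sites(seq, base) <= find_cleavage_sites(seq, extra)


class TestRuleValidation:
    def test_empty_p1_rejected(self):
        with pytest.raises(ValueError):
            CleavageRule(p1=frozenset())

    def test_bad_exception_pattern_rejected(self):
        with pytest.raises(ValueError):
            CleavageRule(p1=frozenset("K"), exceptions=(("K", "P"),))
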