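"""Filter chain: editing-type rule, Alu retention, SNP exclusion."""

from __future__ import annotations

import numpy as np
import pytest

from natedit.filters import (
    FilterReport,
    FilterStage,
    apply_filter_chain,
    filter_alu_overlap,
    filter_editing_type,
    filter_snp_overlap,
)
from natedit.io import GenomicInterval, IntervalSet

from conftest import brute_force_overlap, make_call, make_callset, random_filter_fixture


def interval_set(kind, *triples):
    return IntervalSet(
        kind,
        tuple(GenomicInterval("chrS", a, b, name, ".") for a, b, name in triples),
    )


class TestEditingTypeRule:
    FIVE = [
        ("A>G", "+", True),
        ("T>C", "-", True),
        ("T>C", "+", False),
        ("A>G", "-", False),
        ("G>A", "+", False),
    ]

    def test_strict_rule_over_enumerated_pairs(self):
        cs = make_callset(
            [make_call(10 * i, substitution=s, strand=st) for i, (s, st, _) in enumerate(self.FIVE)]
        )
        kept = filter_editing_type(cs)
        expected = {10 * i for i, (_, _, keep) in enumerate(self.FIVE) if keep}
        assert {c.start for c in kept} == expected
        assert len(kept) == 2

    def test_lenient_accepts_any_ag_tc(self):
        cs = make_callset(
            [make_call(10 * i, substitution=s, strand=st) for i, (s, st, _) in enumerate(self.FIVE)]
        )
        kept = filter_editing_type(cs, lenient=True)
        assert len(kept) == 4  # everything except G>A


class TestAluOverlap:
    @pytest.mark.parametrize(
        "alu_span, retained",
        [
            ((50, 150), True),    # containment
            ((0, 100), False),    # half-open right boundary
            ((100, 200), True),   # left-closed boundary
            ((101, 200), False),  # just past
        ],
    )
    def test_half_open_boundaries(self, alu_span, retained):
        cs = make_callset([make_call(100)])
        alu = interval_set("alu", (*alu_span, "AluY"))
        assert (len(filter_alu_overlap(cs, alu)) == 1) is retained

    def test_wrong_kind_rejected(self):
        cs = make_callset([make_call(100)])
        nat = interval_set("nat", (50, 150, "NAT1"))
        with pytest.raises(ValueError, match="alu"):
            filter_alu_overlap(cs, nat)


class TestSnpOverlap:
    def test_ag_snp_removes_coincident_call(self):
        cs = make_callset([make_call(100)])
        snps = interval_set("snp", (100, 101, "A>G"))
        out, stage = filter_snp_overlap(cs, snps)
        assert len(out) == 0
        assert stage.excluded_count == 1

    def test_non_ag_tc_snp_does_not_remove(self):
        cs = make_callset([make_call(100)])
        snps = interval_set("snp", (100, 101, "C>T"))
        out, _ = filter_snp_overlap(cs, snps)
        assert len(out) == 1

    def test_positional_mode_removes_on_any_snp(self):
        cs = make_callset([make_call(100)])
        snps = interval_set("snp", (100, 101, "C>T"))
        out, _ = filter_snp_overlap(cs, snps, allele_specific=False)
        assert len(out) == 0

    def test_excluded_fraction_arithmetic(self):
        calls = [make_call(i) for i in range(1000)]
        snps = interval_set("snp", *[(i, i + 1, "A>G") for i in range(10)])
        out, stage = filter_snp_overlap(make_callset(calls), snps)
        assert len(out) == 990
        assert stage.excluded_fraction == pytest.approx(0.010)


def disjoint_fixture():
    """10 calls with disjoint violation categories.

    2 wrong editing type, 3 outside Alu, 1 on an A>G SNP, 4 clean.
    """
    calls = [
        make_call(10),                                  # clean
        make_call(20, substitution="T>C", strand="-"),  # clean
        make_call(30),                                  # clean
        make_call(40),                                  # clean
        make_call(50, substitution="C>T"),              # wrong type
        make_call(60, substitution="A>G", strand="-"),  # wrong type (strict)
        make_call(110),                                 # outside Alu
        make_call(120),                                 # outside Alu
        make_call(130),                                 # outside Alu
        make_call(70),                                  # SNP-coincident
    ]
    alu = interval_set("alu", (0, 100, "AluY"))
    snps = interval_set("snp", (70, 71, "A>G"))
    return make_callset(calls), alu, snps


class TestFilterChain:
    def test_disjoint_fixture_retains_four(self):
        cs, alu, snps = disjoint_fixture()
        out, report = apply_filter_chain(cs, alu, snps)
        assert {c.start for c in out} == {10, 20, 30, 40}
        stages = {s.stage: s for s in report.stages}
        assert stages["editing_type"].excluded_count == 2
        assert stages["alu_overlap"].excluded_count == 3
        assert stages["snp_overlap"].excluded_count == 1

    def test_counts_conserved_at_every_stage(self):
        cs, alu, snps = disjoint_fixture()
        _, report = apply_filter_chain(cs, alu, snps)
        for s in report.stages:
            assert s.retained_count + s.excluded_count == s.input_count
            assert 0.0 <= s.excluded_fraction <= 1.0

    def test_empty_input_all_counts_zero(self):
        cs, alu, snps = disjoint_fixture()
        out, report = apply_filter_chain(cs.with_calls([]), alu, snps)
        assert len(out) == 0
        assert all(s.input_count == 0 and s.excluded_fraction == 0.0 for s in report.stages)

    def test_chain_is_idempotent(self):
        cs, alu, snps = disjoint_fixture()
        once, _ = apply_filter_chain(cs, alu, snps)
        twice, report = apply_filter_chain(once, alu, snps)
        assert twice.calls == once.calls
        assert all(s.excluded_count == 0 for s in report.stages)

    def test_alu_and_snp_stages_commute(self):
        cs, alu, snps = disjoint_fixture()
        typed = filter_editing_type(cs)
        a_then_s, _ = filter_snp_overlap(filter_alu_overlap(typed, alu), snps)
        s_first, _ = filter_snp_overlap(typed, snps)
        s_then_a = filter_alu_overlap(s_first, alu)
        assert a_then_s.calls == s_then_a.calls

    def test_stage_ledger_rejects_inconsistent_counts(self):
        with pytest.raises(ValueError, match="input"):
            FilterReport(
                stages=(FilterStage("a", 10, 8), FilterStage("b", 9, 9))
            )


class TestBruteForceEquivalence:
    @pytest.mark.parametrize("seed", range(20))
    def test_tree_overlap_equals_all_pairs_scan(self, seed):
        rng = np.random.default_rng(seed)
        cs, alu, snps = random_filter_fixture(rng)
        tree_kept = {c.sort_key() for c in filter_alu_overlap(cs, alu)}
        brute_kept = {c.sort_key() for c in cs if brute_force_overlap(c, alu)}
        assert tree_kept == brute_kept

    @pytest.mark.parametrize("seed", range(10))
    def test_chain_output_is_subset_of_input(self, seed):
        rng = np.random.default_rng(100 + seed)
        cs, alu, snps = random_filter_fixture(rng)
        out, report = apply_filter_chain(cs, alu, snps)
        assert set(c.sort_key() for c in out) <= set(c.sort_key() for c in cs)
        assert report.retained_count == len(out)
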