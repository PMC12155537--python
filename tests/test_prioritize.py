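"""Prevalence statistics, ratio Z-scores, and candidate selection."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from natedit.io import GenomicInterval, IntervalSet
from natedit.prioritize import (
    intersect_subtypes,
    prevalence_filter,
    prevalence_ratio,
    prioritize,
    select_candidates,
    site_prevalence,
    zscore_ratios,
    CandidateList,
)

from conftest import cohort_from_k_table, make_call, make_callset


def nat_set(*spans):
    return IntervalSet(
        "nat",
        tuple(GenomicInterval("chrS", a, b, f"NAT{i}", "-") for i, (a, b) in enumerate(spans)),
    )


def records_frame(rows):
    """rows: (chrom, start, k_t, n_t, k_a, n_a)."""
    df = pd.DataFrame(rows, columns=["chrom", "start", "k_tumor", "n_tumor",
                                     "k_adjacent", "n_adjacent"])
    df["prev_tumor"] = df["k_tumor"] / df["n_tumor"]
    df["prev_adjacent"] = df["k_adjacent"] / df["n_adjacent"]
    return df


class TestSitePrevalence:
    def test_half_detected_in_study_sized_group(self):
        sets = cohort_from_k_table({100: (21, 0)}, n_tumor=42, n_adjacent=30)
        df = site_prevalence(sets)
        assert df.loc[0, "k_tumor"] == 21
        assert df.loc[0, "n_tumor"] == 42
        assert df.loc[0, "prev_tumor"] == pytest.approx(0.5)

    def test_roster_is_union_of_observed_sites(self):
        sets = cohort_from_k_table({100: (2, 0), 200: (0, 3)}, n_tumor=4, n_adjacent=4)
        df = site_prevalence(sets)
        assert set(df["start"]) == {100, 200}

    def test_site_in_every_sample(self):
        sets = cohort_from_k_table({100: (4, 4)}, n_tumor=4, n_adjacent=4)
        df = site_prevalence(sets)
        assert df.loc[0, "prev_tumor"] == 1.0
        assert df.loc[0, "prev_adjacent"] == 1.0

    def test_empty_group_rejected(self):
        sets = [make_callset([make_call(1)], group="tumor")]
        with pytest.raises(ValueError, match="per group"):
            site_prevalence(sets)


class TestPrevalenceFilter:
    @pytest.mark.parametrize(
        "prev_t, prev_a, kept",
        [
            (0.50, 0.10, True),
            (0.40, 0.00, True),    # inclusive boundary
            (0.00, 0.40, True),    # either group qualifies
            (0.39, 0.39, False),
        ],
    )
    def test_forty_percent_rule(self, prev_t, prev_a, kept):
        df = records_frame([("chrS", 100, round(prev_t * 100), 100,
                             round(prev_a * 100), 100)])
        out = prevalence_filter(df)
        assert (len(out) == 1) is kept

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            prevalence_filter(records_frame([]), min_prevalence=1.5)


class TestPrevalenceRatio:
    def test_plain_ratio(self):
        df = prevalence_ratio(records_frame([("chrS", 1, 5, 10, 1, 10)]))
        assert df.loc[0, "ratio"] == pytest.approx(5.0)

    def test_equal_prevalence_gives_unit_ratio(self):
        df = prevalence_ratio(records_frame([("chrS", 1, 6, 10, 6, 10)]))
        assert df.loc[0, "ratio"] == pytest.approx(1.0)
        assert df.loc[0, "log2_ratio"] == pytest.approx(0.0)

    def test_zero_adjacent_guarded_with_half_count(self):
        df = prevalence_ratio(records_frame([("chrS", 1, 10, 25, 0, 25)]))
        # prev 0.4 divided by 0.5/25 = 0.02
        assert df.loc[0, "ratio"] == pytest.approx(20.0)

    def test_haldane_shrinkage(self):
        df = prevalence_ratio(records_frame([("chrS", 1, 10, 19, 0, 19)]),
                              shrinkage="haldane")
        assert df.loc[0, "ratio"] == pytest.approx((10.5 / 20) / (0.5 / 20))


class TestZScores:
    def _frame(self, ratios):
        df = records_frame([("chrS", 10 * (i + 1), 1, 2, 1, 2) for i in range(len(ratios))])
        df["ratio"] = ratios
        df["log2_ratio"] = np.log2(df["ratio"])
        return df

    def test_hand_computed_classical_z(self):
        df = zscore_ratios(self._frame([1, 2, 3, 4, 5]), scale="raw")
        # sample sd of 1..5 is sqrt(2.5); last record: (5 - 3)/sqrt(2.5)
        assert df["z"].iloc[-1] == pytest.approx(2 / math.sqrt(2.5), abs=1e-9)
        assert df["z"].iloc[-1] == pytest.approx(1.2649110640, abs=1e-6)

    def test_degenerate_equal_ratios_warn_and_zero(self):
        with pytest.warns(UserWarning, match="equal"):
            df = zscore_ratios(self._frame([2, 2, 2, 2]), scale="raw")
        assert (df["z"] == 0.0).all()

    def test_standardization_identity(self):
        rng = np.random.default_rng(7)
        df = zscore_ratios(self._frame(list(rng.lognormal(0, 1, 50))))
        assert df["z"].mean() == pytest.approx(0.0, abs=1e-9)
        assert df["z"].std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_robust_z_ignores_a_single_outlier(self):
        values = [1.0] * 10 + [1.2] * 10 + [0.8] * 10 + [50.0]
        classical = zscore_ratios(self._frame(values), scale="raw")
        robust = zscore_ratios(self._frame(values), scale="raw", method="robust")
        assert robust["z"].iloc[-1] > 10 * classical["z"].iloc[-1]

    def test_external_reference_values(self):
        df = zscore_ratios(self._frame([10.0]), scale="raw",
                           reference_values=[1.0, 2.0, 3.0])
        assert df["z"].iloc[0] == pytest.approx((10 - 2) / 1.0, abs=1e-9)

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            zscore_ratios(self._frame([1.0, 2.0]))


class TestSelectCandidates:
    def _records(self, z_and_start):
        df = records_frame([("chrS", s, 5, 10, 1, 10) for _, s in z_and_start])
        df["ratio"] = 5.0
        df["log2_ratio"] = np.log2(5.0)
        df["z"] = [z for z, _ in z_and_start]
        return df

    def test_nat_overlap_required(self):
        df = self._records([(2.5, 100), (2.5, 900)])
        nat = nat_set((50, 150))
        sel = select_candidates(df, nat)
        assert list(sel.records["start"]) == [100]

    def test_threshold_is_strict(self):
        df = self._records([(1.96, 100), (-1.9599999, 200), (2.0, 300)])
        nat = nat_set((0, 1000))
        sel = select_candidates(df, nat)
        assert list(sel.records["start"]) == [300]

    def test_ordered_by_abs_z_descending(self):
        df = self._records([(2.0, 100), (-3.5, 200), (2.9, 300)])
        nat = nat_set((0, 1000))
        sel = select_candidates(df, nat)
        assert list(sel.records["start"]) == [200, 300, 100]

    def test_wrong_interval_kind_rejected(self):
        df = self._records([(2.5, 100)])
        alu = IntervalSet("alu", (GenomicInterval("chrS", 0, 1000, "AluY", "+"),))
        with pytest.raises(ValueError, match="nat"):
            select_candidates(df, alu)


class TestIntersectSubtypes:
    def _candidates(self, starts, subtype):
        df = records_frame([("chr7", s, 5, 10, 1, 10) for s in starts])
        df["z"] = 3.0
        return CandidateList(subtype=subtype, records=df, min_prevalence=0.4,
                             z_threshold=1.96)

    def test_shared_site_reported(self):
        """Both subtype lists contain the same site -> single shared event."""
        er = self._candidates([77_056_247, 500], "ER+")
        tnbc = self._candidates([77_056_247, 900], "TNBC")
        shared = intersect_subtypes(er, tnbc)
        assert shared == [("chr7", 77_056_247)]
        # reported 1-based, matching the published coordinate style
        from natedit.prioritize import format_sites_report

        assert format_sites_report(shared) == ["chr7:77056248"]

    def test_disjoint_lists(self):
        assert intersect_subtypes(self._candidates([1], "ER+"),
                                  self._candidates([2], "TNBC")) == []

    def test_identical_lists(self):
        a = self._candidates([1, 2, 3], "ER+")
        assert intersect_subtypes(a, a) == [("chr7", 1), ("chr7", 2), ("chr7", 3)]


class TestPipelineProperties:
    def _cohort(self):
        # one strong site, several unremarkable ones
        k = {100: (9, 1), 200: (5, 5), 300: (6, 5), 400: (4, 5),
             500: (5, 4), 600: (6, 6), 700: (5, 6), 800: (2, 2)}
        return cohort_from_k_table(k, n_tumor=10, n_adjacent=10)

    def test_candidate_set_shrinks_with_stricter_parameters(self):
        sets = self._cohort()
        nat = nat_set((0, 1000))
        base = prioritize(sets, nat).candidates.sites()
        higher_prev = prioritize(sets, nat, min_prevalence=0.6).candidates.sites()
        higher_z = prioritize(sets, nat, z_threshold=3.5).candidates.sites()
        assert higher_prev <= base
        assert higher_z <= base

    def test_group_swap_negates_log2_ratio(self):
        sets = self._cohort()
        swapped = [
            make_callset(cs.calls, sample_id=cs.sample_id,
                         group="adjacent" if cs.group == "tumor" else "tumor",
                         subtype=cs.subtype, mapped_reads=cs.mapped_reads)
            for cs in sets
        ]
        fwd = prevalence_ratio(site_prevalence(sets)).set_index("start")
        rev = prevalence_ratio(site_prevalence(swapped)).set_index("start")
        for start in fwd.index:
            assert rev.loc[start, "log2_ratio"] == pytest.approx(
                -fwd.loc[start, "log2_ratio"], abs=1e-12
            )

    def test_classical_and_robust_modes_run_end_to_end(self):
        sets = self._cohort()
        nat = nat_set((0, 1000))
        classical = prioritize(sets, nat, ratio_scale="log2", z_method="classical",
                               z_reference="postfilter", shrinkage=None)
        robust = prioritize(sets, nat)
        assert {"ratio", "log2_ratio", "z"} <= set(classical.candidates.records.columns)
        assert {"ratio", "log2_ratio", "z"} <= set(robust.candidates.records.columns)
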