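"""Allele tables, the support filter, cohort summaries and the Surveyor estimator."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ampliclone.align import RawIndelObservation
from ampliclone.calling import (
    FilterParams,
    GelBands,
    SiteAlleleTable,
    compute_cohort_summary,
    filter_indels,
    offtarget_screen,
    pileup_site,
    scaled_filter_params,
    surveyor_indel_fraction,
)
from ampliclone.simulate import IndelAllele


def _obs(pair_id, pos=100, typ="del", length=3, seq="AAA"):
    return RawIndelObservation("s1", pos, typ, length, seq, pair_id)


def _table(site_id, supports, spanning, unassigned=0):
    alleles = [
        (IndelAllele(100 + i, "del", 3, "AAA"), n, n / spanning)
        for i, n in enumerate(supports)
    ]
    return SiteAlleleTable(
        site_id, spanning, alleles, spanning - sum(supports) - unassigned, unassigned
    )


class TestPileup:
    def test_no_observations_all_wild_type(self):
        t = pileup_site([], 1000, None)
        assert t.wt_reads == 1000
        assert t.cumulative_mrf == 0.0

    def test_identical_indels_merge(self):
        t = pileup_site([_obs("p1"), _obs("p2")], 10)
        assert len(t.alleles) == 1
        allele, support, mrf = t.alleles[0]
        assert support == 2 and mrf == pytest.approx(0.2)

    def test_distinct_indels_stay_separate(self):
        t = pileup_site([_obs("p1"), _obs("p2", pos=105)], 10)
        assert len(t.alleles) == 2

    def test_multi_indel_pair_goes_to_unassigned(self):
        t = pileup_site([_obs("p1"), _obs("p1", pos=105)], 10)
        assert t.alleles == []
        assert t.unassigned == 1
        t.validate()

    def test_observations_exceeding_spanning_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            pileup_site([_obs("p1"), _obs("p2", pos=105)], 1)

    def test_count_conservation(self):
        t = pileup_site([_obs(f"p{i}") for i in range(7)], 50)
        assert t.wt_reads + sum(s for _a, s, _m in t.alleles) + t.unassigned == 50


class TestFilter:
    def test_support_at_threshold_removed(self):
        """Exactly 100 supporting reads fails the strictly-greater rule."""
        t = _table("s", [100], 10_000)
        out = filter_indels(t, FilterParams())
        assert out.alleles == [] and out.unassigned == 100

    def test_support_above_threshold_retained(self):
        t = _table("s", [101], 10_000)
        out = filter_indels(t, FilterParams())
        assert len(out.alleles) == 1

    def test_error_floor_removes_low_mrf(self):
        t = _table("s", [120], 100_000)  # mrf 0.0012 < 0.005
        out = filter_indels(t, FilterParams())
        assert out.alleles == []

    def test_identity_at_zero_thresholds(self):
        t = _table("s", [5, 50], 1000)
        out = filter_indels(t, FilterParams(0, 0.0))
        assert sorted(s for _a, s, _m in out.alleles) == [5, 50]

    @given(st.integers(0, 30), st.integers(0, 30))
    @settings(max_examples=40, deadline=None)
    def test_monotone_in_support_threshold(self, lo, hi):
        """Raising min_mutant_reads never adds alleles."""
        t = _table("s", [5, 12, 25], 1000)
        lo, hi = min(lo, hi), max(lo, hi)
        few = filter_indels(t, FilterParams(hi, 0.0))
        many = filter_indels(t, FilterParams(lo, 0.0))
        kept_few = {a.identity for a, _s, _m in few.alleles}
        kept_many = {a.identity for a, _s, _m in many.alleles}
        assert kept_few <= kept_many

    def test_scaled_params_floor(self):
        assert scaled_filter_params(500).min_mutant_reads == 10
        assert scaled_filter_params(5000).min_mutant_reads == 50


class TestCohortSummary:
    def test_single_insertion_sample(self):
        t = SiteAlleleTable(
            "s1", 100, [(IndelAllele(10, "ins", 2, "AT"), 60, 0.6)], 40
        )
        summary = compute_cohort_summary({"samp": {"s1": t}})
        assert summary["insertion_fraction"] == 1.0
        assert summary["insertion_size_range"] == (2, 2)
        assert summary["deletion_size_range"] is None

    def test_gene_collapsing(self):
        t1 = SiteAlleleTable("gA-ex1", 100, [(IndelAllele(1, "del", 1, "A"), 50, 0.5)], 50)
        t2 = SiteAlleleTable("gA-ex2", 100, [(IndelAllele(2, "del", 2, "AT"), 50, 0.5)], 50)
        summary = compute_cohort_summary(
            {"samp": {"gA-ex1": t1, "gA-ex2": t2}},
            site_to_gene={"gA-ex1": "gA", "gA-ex2": "gA"},
        )
        assert summary["mutated_genes_per_sample"]["samp"] == 1

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            compute_cohort_summary({})


class TestOfftargetScreen:
    def test_verdicts(self):
        wt = _table("ot1", [], 500)
        low = _table("ot2", [3], 500)      # below scaled threshold
        mut = _table("ot3", [150], 500)
        empty = _table("ot4", [], 0)
        frame = offtarget_screen(
            {"cl1": {"ot1": wt, "ot2": low, "ot3": mut, "ot4": empty}},
            scaled_filter_params(500),
        )
        verdicts = dict(zip(frame["site_id"], frame["verdict"]))
        assert verdicts == {
            "ot1": "wild_type_only",
            "ot2": "wild_type_only",
            "ot3": "mutated",
            "ot4": "no_data",
        }

    def test_positions_counted_per_sample_site(self):
        wt = _table("ot1", [], 100)
        frame = offtarget_screen(
            {"a": {"ot1": wt}, "b": {"ot1": wt}}, FilterParams(10, 0.005)
        )
        assert len(frame) == 2


class TestSurveyor:
    @pytest.mark.parametrize(
        "uncut,cut,expected",
        [
            (1.0, (), 0.0),
            (0.81, (0.19,), 0.10),   # 1 - sqrt(0.81)
            (0.25, (0.50, 0.25), 0.50),  # 1 - sqrt(0.25)
        ],
    )
    def test_duplex_correction_analytic_values(self, uncut, cut, expected):
        assert surveyor_indel_fraction(GelBands(uncut, cut)) == pytest.approx(
            expected, abs=1e-12
        )

    def test_saturated_assay_warns_and_returns_one(self):
        with pytest.warns(UserWarning, match="saturated"):
            assert surveyor_indel_fraction(GelBands(0.0, (1.0,))) == 1.0

    def test_zero_total_intensity_rejected(self):
        with pytest.raises(ValueError):
            GelBands(0.0, (0.0,))

    @given(st.floats(0.0, 0.99), st.floats(0.0, 0.99))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_cleaved_fraction(self, f1, f2):
        f1, f2 = min(f1, f2), max(f1, f2)
        v1 = surveyor_indel_fraction(GelBands(1 - f1, (f1,)))
        v2 = surveyor_indel_fraction(GelBands(1 - f2, (f2,)))
        assert v1 <= v2 + 1e-12
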