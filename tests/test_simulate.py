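"""Generator statistics, ground-truth bookkeeping and determinism."""

import numpy as np
import pytest

from ampliclone.panel import simulate_panel
from ampliclone.simulate import (
    CloneTruth,
    IndelAllele,
    IndelModel,
    SampleTruth,
    SimConfig,
    apply_indel,
    expected_site_fractions,
    metastasis_clone,
    sample_indel,
    simulate_clone,
    simulate_cohort,
    simulate_junction_amplicon,
    simulate_sample_reads,
)


class TestIndelModel:
    def test_point_mass_deletion_at_cut(self, small_panel, rng):
        model = IndelModel(
            p_deletion=1.0, del_max=3, del_len_probs=(0.0, 0.0, 1.0), pos_jitter=0
        )
        site = small_panel[0]
        allele = sample_indel(model, site, rng)
        assert allele.type == "del" and allele.length == 3
        # left-alignment may shift within a repeat, never rightwards
        assert allele.pos <= site.cut_pos - 1

    def test_deletion_bias_matches_configured_rate(self, small_panel, rng):
        """Over 10,000 draws the deletion fraction sits within 3 s.d. of 0.9
        and sizes respect the 1-363 / 1-32 bounds."""
        model = IndelModel()
        site = small_panel[0]
        draws = [sample_indel(model, site, rng) for _ in range(10_000)]
        n_del = sum(1 for a in draws if a.type == "del")
        sd = np.sqrt(0.9 * 0.1 / 10_000)
        assert abs(n_del / 10_000 - 0.9) < 3 * sd
        del_lens = [a.length for a in draws if a.type == "del"]
        ins_lens = [a.length for a in draws if a.type == "ins"]
        assert min(del_lens) >= 1 and max(del_lens) <= 363
        assert min(ins_lens) >= 1 and max(ins_lens) <= 32

    def test_inverse_size_frequency_relation(self, small_panel, rng):
        model = IndelModel()
        site = small_panel[0]
        lens = [
            sample_indel(model, site, rng).length
            for _ in range(5000)
        ]
        small = sum(1 for l in lens if l <= 5)
        large = sum(1 for l in lens if l > 20)
        assert small > 5 * large

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            IndelModel(p_deletion=1.5)
        with pytest.raises(ValueError):
            IndelModel(del_len_probs=(0.5, 0.2))  # wrong support


class TestCloneAndSampleTruth:
    def test_allele_slots_match_ploidy(self, small_panel, rng):
        clone = simulate_clone(
            "c1", small_panel, {s.chrom: 3 for s in small_panel},
            IndelModel(), rng,
        )
        for site in small_panel:
            assert len(clone.copies(site)) == 3
        clone.validate(small_panel)

    def test_blocked_gene_never_edited(self, small_panel, rng):
        blocked = small_panel[0].site_id
        for _ in range(10):
            clone = simulate_clone(
                "c", small_panel, {s.chrom: 2 for s in small_panel},
                IndelModel(), rng, p_delivery=1.0, p_copy_edit=1.0,
                blocked_genes=(blocked,),
            )
            assert all(sid != blocked for sid, _ in clone.signature())

    def test_mixture_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SampleTruth("s", "cell_line", {"c": 0.5}, 0.2)

    def test_metastasis_requires_parent(self):
        with pytest.raises(ValueError, match="parent_primary"):
            SampleTruth("m", "metastasis", {"c": 1.0}, 0.0)

    def test_metastasis_signature_equals_parent(self, small_panel, rng):
        parent = simulate_clone(
            "p", small_panel, {s.chrom: 2 for s in small_panel}, IndelModel(), rng
        )
        met = metastasis_clone(parent, "m")
        assert met.signature() == parent.signature()


class TestExpectedFractions:
    def test_fractions_sum_to_one_everywhere(self, small_panel, rng):
        clone = simulate_clone(
            "c", small_panel, {s.chrom: 4 for s in small_panel}, IndelModel(), rng
        )
        sample = SampleTruth("s", "tumour_tissue", {"c": 0.7}, 0.3)
        for site in small_panel:
            fracs = expected_site_fractions(sample, {"c": clone}, site)
            assert abs(sum(fracs.values()) - 1.0) < 1e-12

    def test_normal_sample_is_all_wild_type(self, small_panel):
        sample = SampleTruth("n", "normal", {}, 1.0)
        for site in small_panel:
            fracs = expected_site_fractions(sample, {}, site)
            assert fracs == {None: 1.0}

    def test_heterozygous_diploid_gives_half(self, small_panel, rng):
        site = small_panel[0]
        allele = sample_indel(IndelModel(), site, rng)
        clone = CloneTruth(
            "c", {s.chrom: 2 for s in small_panel},
            {(site.site_id, 0): allele, (site.site_id, 1): None},
        )
        sample = SampleTruth("s", "cell_line", {"c": 1.0}, 0.0)
        fracs = expected_site_fractions(sample, {"c": clone}, site)
        assert fracs[allele] == pytest.approx(0.5)
        assert fracs[None] == pytest.approx(0.5)


class TestJunctionAmplicons:
    def test_intra_deletion_single_junction_at_cuts(self, small_panel):
        a, b = small_panel[0], small_panel[1]
        juncs = simulate_junction_amplicon(a, b, "intra_deletion")
        assert len(juncs) == 1
        _jid, seq = juncs[0]
        assert seq == a.amplicon_seq[: a.cut_pos] + b.amplicon_seq[b.cut_pos :]

    def test_reciprocal_emits_both_derivatives(self, small_panel):
        juncs = simulate_junction_amplicon(
            small_panel[0], small_panel[1], "translocation_reciprocal"
        )
        assert len(juncs) == 2

    def test_nonreciprocal_single_derivative(self, small_panel):
        juncs = simulate_junction_amplicon(
            small_panel[0], small_panel[1], "translocation_nonreciprocal"
        )
        assert len(juncs) == 1

    def test_self_junction_rejected(self, small_panel):
        with pytest.raises(ValueError):
            simulate_junction_amplicon(small_panel[0], small_panel[0], "intra_deletion")


class TestCohortSimulation:
    def _tiny_cohort(self, panel, rng, coverage=50):
        clone = simulate_clone(
            "c", panel, {s.chrom: 2 for s in panel}, IndelModel(), rng
        )
        samples = [
            SampleTruth("tum", "cell_line", {"c": 1.0}, 0.0),
            SampleTruth("norm", "normal", {}, 1.0),
        ]
        config = SimConfig(seed=77, coverage_per_site=coverage)
        return {"c": clone}, samples, config

    def test_fixed_seed_bit_identical_outputs(self, small_panel, rng, tmp_path):
        clones, samples, config = self._tiny_cohort(small_panel, rng)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_cohort(config, small_panel, clones, samples, out_dir=d1)
        simulate_cohort(config, small_panel, clones, samples, out_dir=d2)
        for f1 in sorted(d1.iterdir()):
            assert f1.read_bytes() == (d2 / f1.name).read_bytes()

    def test_zero_coverage_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(coverage_per_site=0)

    def test_unknown_rearrangement_site_rejected(self, small_panel, rng):
        clones, samples, config = self._tiny_cohort(small_panel, rng)
        clones["c"].rearrangements = [("nope", small_panel[0].site_id, "intra_deletion")]
        with pytest.raises(ValueError, match="unknown site"):
            simulate_cohort(config, small_panel, clones, samples)

    def test_truth_tables_written(self, small_panel, rng, tmp_path):
        clones, samples, config = self._tiny_cohort(small_panel, rng)
        simulate_cohort(config, small_panel, clones, samples, out_dir=tmp_path)
        for name in ("clone_alleles", "sample_mixtures", "expected_mrfs"):
            assert (tmp_path / f"truth_{name}.tsv").exists()
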