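"""Indel-barcode lineage tracking: distances, clustering, origin assignment."""

import itertools

import numpy as np
import pytest

from ampliclone.calling import SiteAlleleTable
from ampliclone.lineage import (
    CloneSignature,
    assign_metastases,
    build_signature,
    deconvolve_primaries,
    dendrogram_newick,
    origin_fractions,
    signature_distance,
)
from ampliclone.simulate import IndelAllele


def _sig(sample_id, markers):
    return CloneSignature(sample_id, frozenset(markers))


def _marker(i, site="s1"):
    return (site, (100 + i, "del", 2, "AT"))


class TestBuildSignature:
    def test_empty_tables_empty_signature(self):
        t = SiteAlleleTable("s1", 100, [], 100)
        assert build_signature({"s1": t}, "x").markers == frozenset()

    def test_deterministic(self):
        t = SiteAlleleTable(
            "s1", 100, [(IndelAllele(5, "del", 2, "AT"), 60, 0.6)], 40
        )
        a = build_signature({"s1": t}, "x")
        b = build_signature({"s1": t}, "x")
        assert a == b

    def test_relaxed_mode_drops_sequence(self):
        t = SiteAlleleTable(
            "s1", 100, [(IndelAllele(5, "del", 2, "AT"), 60, 0.6)], 40
        )
        sig = build_signature({"s1": t}, "x", relaxed=True)
        assert sig.markers == {("s1", (5, "del", 2))}


class TestSignatureDistance:
    def test_identical_nonempty_is_zero(self):
        s = _sig("a", [_marker(1), _marker(2)])
        assert signature_distance(s, _sig("b", [_marker(1), _marker(2)])) == 0.0

    def test_disjoint_is_one(self):
        assert signature_distance(
            _sig("a", [_marker(1)]), _sig("b", [_marker(2)])
        ) == 1.0

    def test_half_overlap(self):
        a = _sig("a", [_marker(i) for i in range(8)])
        b = _sig("b", [_marker(i) for i in range(5, 12)])
        # |intersection| = 3, |union| = 12
        assert signature_distance(a, b) == pytest.approx(1 - 3 / 12)

    def test_both_empty_warns_and_is_one(self):
        with pytest.warns(UserWarning):
            assert signature_distance(_sig("a", []), _sig("b", [])) == 1.0

    def test_metric_axioms_on_small_sets(self):
        """Identity, symmetry and the triangle inequality, by enumeration."""
        universe = [_marker(i) for i in range(4)]
        sets = [
            _sig(f"s{i}", combo)
            for i, combo in enumerate(
                itertools.chain.from_iterable(
                    itertools.combinations(universe, r) for r in range(1, 4)
                )
            )
        ]
        for a, b, c in itertools.product(sets, repeat=3):
            dab = signature_distance(a, b)
            assert dab == signature_distance(b, a)
            if a.markers == b.markers:
                assert dab == 0.0
            assert dab <= signature_distance(a, c) + signature_distance(c, b) + 1e-12


class TestDeconvolvePrimaries:
    def _two_tumour_cohort(self):
        tu1 = [_marker(i) for i in range(5)]
        tu2 = [_marker(i, site="s2") for i in range(4)]
        sigs = [_sig(f"biopsy_{i}", tu1) for i in range(2, 8)]
        sigs.append(_sig("biopsy_1", tu1 + tu2))       # mixed biopsy
        sigs.append(_sig("clone_A", tu1))              # single-cell clones
        sigs.append(_sig("clone_B", tu2))
        return sigs, tu1, tu2

    def test_mixed_biopsy_detected_and_clusters_split(self):
        sigs, tu1, tu2 = self._two_tumour_cohort()
        res = deconvolve_primaries(sigs)
        assert len(res.clusters) == 2
        assert list(res.mixed) == ["biopsy_1"]
        comps = res.mixed_components["biopsy_1"]
        assert set(map(frozenset, comps.values())) == {frozenset(tu1), frozenset(tu2)}

    def test_pure_biopsies_never_flagged_mixed(self):
        sigs, _tu1, _tu2 = self._two_tumour_cohort()
        res = deconvolve_primaries(sigs)
        assert not any(s.startswith("biopsy_") and s != "biopsy_1" for s in res.mixed)

    def test_identical_signatures_one_cluster(self):
        sigs = [_sig(f"x{i}", [_marker(1), _marker(2)]) for i in range(4)]
        res = deconvolve_primaries(sigs)
        assert len(res.clusters) == 1 and not res.mixed

    def test_three_disjoint_clones_recovered(self):
        sigs = []
        for c in range(3):
            markers = [_marker(i, site=f"site{c}") for i in range(4)]
            sigs += [_sig(f"c{c}_rep{r}", markers) for r in range(3)]
        res = deconvolve_primaries(sigs)
        assert len(res.clusters) == 3
        for cluster in res.clusters:
            assert len({s.split("_")[0] for s in cluster}) == 1

    def test_invariant_to_input_order(self):
        sigs, _t1, _t2 = self._two_tumour_cohort()
        res1 = deconvolve_primaries(sigs)
        rng = np.random.default_rng(5)
        shuffled = list(sigs)
        rng.shuffle(shuffled)
        res2 = deconvolve_primaries(shuffled)
        assert res1.clusters == res2.clusters
        assert res1.mixed == res2.mixed

    def test_single_signature(self):
        res = deconvolve_primaries([_sig("only", [_marker(1)])])
        assert res.clusters == [["only"]]

    def test_newick_export_contains_all_samples(self):
        sigs, _t1, _t2 = self._two_tumour_cohort()
        res = deconvolve_primaries(sigs)
        nwk = dendrogram_newick(res)
        for sig in sigs:
            assert sig.sample_id in nwk


class TestAssignMetastases:
    def test_disjoint_primaries_perfect_assignment(self):
        tu1 = [_marker(i) for i in range(5)]
        tu2 = [_marker(i, site="s2") for i in range(5)]
        prims = [_sig("Tu1", tu1), _sig("Tu2", tu2)]
        mets = [_sig(f"m{i}", tu1) for i in range(5)] + [
            _sig(f"m{i + 5}", tu2) for i in range(4)
        ]
        out = assign_metastases(mets, prims)
        assert [a.assigned_primary for a in out] == ["Tu1"] * 5 + ["Tu2"] * 4
        fracs = origin_fractions(out)
        assert fracs == {"Tu1": pytest.approx(5 / 9), "Tu2": pytest.approx(4 / 9)}

    def test_empty_met_signature_ambiguous(self):
        prims = [_sig("Tu1", [_marker(1), _marker(2)])]
        out = assign_metastases([_sig("m", [])], prims)
        assert out[0].assigned_primary == "ambiguous"

    def test_equal_sharing_is_ambiguous(self):
        shared = [_marker(1), _marker(2)]
        prims = [_sig("Tu1", shared + [_marker(3)]), _sig("Tu2", shared + [_marker(4)])]
        out = assign_metastases([_sig("m", shared)], prims)
        assert out[0].assigned_primary == "ambiguous"
        assert out[0].margin == 0

    def test_requires_a_primary(self):
        with pytest.raises(ValueError):
            assign_metastases([], [])
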