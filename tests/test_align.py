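"""Aligner correctness: oracle equivalence, large deletions, normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ampliclone.align import (
    ScoringParams,
    align_read,
    assign_and_pair,
    extract_indels,
    left_align_deletion,
    left_align_insertion,
    score_from_ops,
)
from ampliclone.panel import revcomp, simulate_panel
from ampliclone.simulate import IndelAllele, apply_indel

from dp_oracle import oracle_score


def _random_dna(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


class TestOracleEquivalence:
    def test_score_matches_exhaustive_dp_on_random_instances(self):
        """200 random (query, ref) pairs of length <= 60: the production
        aligner's score must equal the exhaustive gap-enumeration oracle."""
        rng = np.random.default_rng(1234)
        params = ScoringParams(min_score_frac=-10.0)  # never unmapped
        for trial in range(200):
            n_ref = int(rng.integers(30, 61))
            ref = _random_dna(rng, n_ref)
            style = trial % 4
            if style == 0:  # unrelated query
                query = _random_dna(rng, int(rng.integers(10, 41)))
            elif style == 1:  # substring with substitutions
                a = int(rng.integers(0, n_ref - 15))
                q = list(ref[a : a + int(rng.integers(10, n_ref - a + 1))])
                for _ in range(int(rng.integers(0, 4))):
                    i = int(rng.integers(0, len(q)))
                    q[i] = "ACGT"[rng.integers(0, 4)]
                query = "".join(q)
            elif style == 2:  # planted deletion (incl. >= long_del_min)
                L = int(rng.integers(1, n_ref - 10))
                a = int(rng.integers(0, n_ref - L))
                query = (ref[:a] + ref[a + L :])[:60]
            else:  # planted insertion
                a = int(rng.integers(0, n_ref))
                ins = _random_dna(rng, int(rng.integers(1, 8)))
                query = (ref[:a] + ins + ref[a:])[:60]
            if not query:
                continue
            got = _aligner_score(query, ref, params)
            want = oracle_score(query, ref, params)
            assert got == want, f"trial {trial}: {got} != {want}"

    def test_score_recomputes_from_operations(self, small_panel):
        site = small_panel[0]
        read = site.amplicon_seq[40:340]
        aln = align_read(read, site)
        assert aln.score == score_from_ops(
            read, site.amplicon_seq, aln.ref_start, aln.ops, ScoringParams()
        )


def _aligner_score(query, ref, params):
    """Run the production aligner against a bare reference sequence."""
    from ampliclone.align import _encode, _fill_matrices, _traceback

    q, r = _encode(query), _encode(ref)
    H, E, F, J = _fill_matrices(
        q, r, params.match, params.mismatch,
        params.gap_open + params.gap_extend, params.gap_extend,
        params.long_del, params.long_del_min,
    )
    score, _ops, _start = _traceback(query, ref, H, E, F, J, params)
    return score


class TestAlignRead:
    def test_exact_substring_is_all_match(self, small_panel):
        site = small_panel[0]
        read = site.amplicon_seq[50:350]
        aln = align_read(read, site)
        assert aln.ops == [("M", 300)]
        assert aln.ref_start == 50
        assert aln.score == 600

    def test_363_bp_deletion_single_operation(self):
        """An allele deleting 363 bp yields one deletion op, not fragments."""
        panel = simulate_panel(1, seed=5, amplicon_length=800)
        site = panel[0]
        start = site.cut_pos - 100
        allele = IndelAllele(start, "del", 363, site.amplicon_seq[start : start + 363])
        read = apply_indel(site.amplicon_seq, allele)[
            start - 150 : start - 150 + 300
        ]
        aln = align_read(read, site)
        dels = [(op, n) for op, n in aln.ops if op == "D"]
        assert dels == [("D", 363)]

    def test_unalignable_read_unmapped(self, small_panel, rng):
        read = _random_dna(rng, 300)
        assert align_read(read, small_panel[0]) is None

    def test_query_consumption_invariant(self, small_panel, rng):
        site = small_panel[0]
        allele = IndelAllele(site.cut_pos, "ins", 12, _random_dna(rng, 12))
        read = apply_indel(site.amplicon_seq, allele)[:300]
        aln = align_read(read, site)
        assert aln.query_consumed() == len(read)


class TestLeftAlignment:
    def test_homopolymer_deletion_normalizes_leftmost(self):
        ref = "ACGTAAAAATCG"
        #       ^ run of A at 4..9; any 2-bp deletion inside normalizes to pos 4
        expected = left_align_deletion(ref, 4, 2)
        for pos in range(4, 8):
            assert left_align_deletion(ref, pos, 2) == expected
        assert expected[0] == 4

    def test_idempotence(self):
        ref = "ACGTAAAAATCG"
        pos, seq = left_align_deletion(ref, 6, 2)
        assert left_align_deletion(ref, pos, 2) == (pos, seq)
        ipos, iseq = left_align_insertion(ref, 7, "AA")
        assert left_align_insertion(ref, ipos, iseq) == (ipos, iseq)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_equivalent_deletions_normalize_identically(self, seed):
        """All deletion placements producing the same mutated sequence
        normalize to the same representation."""
        rng = np.random.default_rng(seed)
        ref = _random_dna(rng, 40)
        L = int(rng.integers(1, 5))
        pos = int(rng.integers(1, len(ref) - L))
        mutated = ref[:pos] + ref[pos + L :]
        canonical = left_align_deletion(ref, pos, L)
        for p in range(len(ref) - L + 1):
            if ref[:p] + ref[p + L :] == mutated:
                assert left_align_deletion(ref, p, L) == canonical


class TestExtractIndels:
    def test_all_match_alignment_yields_nothing(self, small_panel):
        site = small_panel[0]
        aln = align_read(site.amplicon_seq[:350], site)
        assert extract_indels(aln, site) == []

    def test_insertion_at_cut_reported(self, small_panel, rng):
        site = small_panel[0]
        ins = _random_dna(rng, 12)
        pos, seq = left_align_insertion(site.amplicon_seq, site.cut_pos, ins)
        allele = IndelAllele(pos, "ins", 12, seq)
        read = apply_indel(site.amplicon_seq, allele)[:330]
        aln = align_read(read, site)
        obs = extract_indels(aln, site)
        assert [(o.type, o.length, o.seq) for o in obs] == [("ins", 12, seq)]

    def test_non_spanning_alignment_excluded(self, small_panel):
        site = small_panel[0]
        read = site.amplicon_seq[site.cut_pos + 5 : site.cut_pos + 200]
        aln = align_read(read, site)
        assert extract_indels(aln, site) == []

    def test_indel_outside_window_not_reported(self, small_panel):
        site = small_panel[0]
        far = site.cut_pos - 80
        allele = IndelAllele(far, "del", 3, site.amplicon_seq[far : far + 3])
        read = apply_indel(site.amplicon_seq, allele)[:330]
        aln = align_read(read, site)
        assert extract_indels(aln, site, window=20) == []


class TestAssignAndPair:
    def test_fr_pair_same_amplicon_paired(self, small_panel):
        site = small_panel[0]
        r1 = site.amplicon_seq[:300]
        r2 = revcomp(site.amplicon_seq[-300:])
        res = assign_and_pair([("p", r1, r2)], small_panel)
        assert res.n_unpaired == 0
        assert len(res.pairs_by_site[site.site_id]) == 1

    def test_discordant_amplicons_unpaired(self, small_panel):
        r1 = small_panel[0].amplicon_seq[:300]
        r2 = revcomp(small_panel[1].amplicon_seq[-300:])
        res = assign_and_pair([("p", r1, r2)], small_panel)
        assert res.n_unpaired == 1
        assert all(not v for v in res.pairs_by_site.values())

    def test_same_orientation_unpaired(self, small_panel):
        site = small_panel[0]
        r1 = site.amplicon_seq[:300]
        r2 = site.amplicon_seq[50:350]  # both forward
        res = assign_and_pair([("p", r1, r2)], small_panel)
        assert res.n_unpaired == 1

    def test_empty_input_warns(self, small_panel):
        res = assign_and_pair([], small_panel)
        assert res.n_pairs == 0 and res.unpaired_fraction == 0.0

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            assign_and_pair([("p", "ACGT", "ACGT")], [])
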