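"""Independent exhaustive alignment oracle for cross-checking the aligner.

Instead of the production four-state affine recurrence, this oracle
enumerates every gap length explicitly at each cell under the declared
cost law (affine for short gaps, flat for deletions of at least the
long-deletion threshold). O(m * n * (m + n)) — usable only on tiny
instances, which is the point.
"""

from __future__ import annotations

from ampliclone.align import ScoringParams


def gap_cost_del(length: int, p: ScoringParams) -> int:
    affine = p.gap_open + length * p.gap_extend
    if length >= p.long_del_min:
        return max(affine, p.long_del)
    return affine


def gap_cost_ins(length: int, p: ScoringParams) -> int:
    return p.gap_open + length * p.gap_extend


def oracle_score(query: str, ref: str, p: ScoringParams | None = None) -> int:
    """Optimal semi-global score (query global, reference ends free)."""
    p = p or ScoringParams()
    m, n = len(query), len(ref)
    neg = -(10**9)
    best = [[neg] * (n + 1) for _ in range(m + 1)]
    for j in range(n + 1):
        best[0][j] = 0
    for i in range(1, m + 1):
        for j in range(n + 1):
            cands = []
            if j > 0:
                sub = p.match if query[i - 1] == ref[j - 1] else p.mismatch
                if best[i - 1][j - 1] > neg:
                    cands.append(best[i - 1][j - 1] + sub)
            for L in range(1, i + 1):  # insertion of length L
                if best[i - L][j] > neg:
                    cands.append(best[i - L][j] + gap_cost_ins(L, p))
            for L in range(1, j + 1):  # deletion of length L
                if best[i][j - L] > neg:
                    cands.append(best[i][j - L] + gap_cost_del(L, p))
            if cands:
                best[i][j] = max(cands)
    return max(best[m])
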