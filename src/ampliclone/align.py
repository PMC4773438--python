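"""Large-deletion-aware semi-global alignment of amplicon reads.

Standard short-read mappers fragment or soft-clip reads that span deletions
of 100 bp and more, so CRISPR alleles with large deletions are lost during
mapping. The aligner here is a semi-global (query-global, reference ends
free) affine-gap dynamic program augmented with a *long-deletion jump*
state: any reference gap of at least ``long_del_min`` bp can be taken for a
flat cost instead of the affine one, so a single 100-400 bp deletion
outscores a soft-clipped or fragmented representation.

Scoring defaults: match +2, mismatch -4, gap of length L costs
``gap_open + L * gap_extend`` (-6 - L), long deletion (L >= 30) a flat -24.

Indel observations are reported left-aligned against the amplicon
reference, so every equivalent placement inside a repeat normalizes to the
same coordinate.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import edlib
import numpy as np
from numba import njit

from .panel import TargetSite, revcomp

logger = logging.getLogger(__name__)

_NEG = -(10**9)


@dataclass(frozen=True)
class ScoringParams:
    match: int = 2
    mismatch: int = -4
    gap_open: int = -6
    gap_extend: int = -1
    long_del: int = -24          # flat cost of one deletion >= long_del_min
    long_del_min: int = 30
    min_score_frac: float = 0.25  # unmapped below this fraction of the perfect score


@dataclass
class AmpliconAlignment:
    """Alignment of one read against one amplicon reference.

    ``ops`` is an ordered list of (op, length) with op in {"M", "I", "D"}:
    M consumes both sequences (match or mismatch), I consumes the query
    (insertion in the read), D consumes the reference (deletion).
    """

    site_id: str
    query: str
    ref_start: int
    ops: list[tuple[str, int]]
    score: int

    @property
    def ref_end(self) -> int:
        return self.ref_start + sum(n for op, n in self.ops if op in "MD")

    def spans(self, lo: int, hi: int) -> bool:
        """True if the aligned reference span covers [lo, hi)."""
        return self.ref_start <= lo and self.ref_end >= hi

    def query_consumed(self) -> int:
        return sum(n for op, n in self.ops if op in "MI")

    def is_clipped(self, max_overhang: int = 5) -> bool:
        """True when the read hangs over the alignment as a long terminal
        insertion — the footprint of a read that only partially belongs to
        this reference (e.g. one side of an unanticipated fusion)."""
        if not self.ops:
            return True
        for op, n in (self.ops[0], self.ops[-1]):
            if op == "I" and n > max_overhang:
                return True
        return False


@dataclass(frozen=True)
class RawIndelObservation:
    """A normalized (left-aligned) indel seen in one read."""

    site_id: str
    pos: int        # 0-based leftmost-normalized reference offset
    type: str       # "del" or "ins"
    length: int
    seq: str        # deleted reference bases or inserted read bases
    pair_id: str = ""

    @property
    def identity(self) -> tuple[str, int, str, int, str]:
        """Exact allele identity, independent of the observing read."""
        return (self.site_id, self.pos, self.type, self.length, self.seq)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


@njit(cache=True)
def _fill_matrices(q, r, match, mismatch, open_ext, ext, jump, jump_min):  # pragma: no cover
    m = q.shape[0]
    n = r.shape[0]
    H = np.full((m + 1, n + 1), _NEG, np.int32)
    E = np.full((m + 1, n + 1), _NEG, np.int32)  # insertion state (consumes query)
    F = np.full((m + 1, n + 1), _NEG, np.int32)  # affine deletion state
    J = np.full((m + 1, n + 1), _NEG, np.int32)  # long-deletion jump state
    for j in range(n + 1):
        H[0, j] = 0  # free reference prefix
    for i in range(1, m + 1):
        e0 = H[i - 1, 0] + open_ext
        if E[i - 1, 0] + ext > e0:
            e0 = E[i - 1, 0] + ext
        E[i, 0] = e0
        H[i, 0] = e0
        rmax = _NEG
        for j in range(1, n + 1):
            jj = j - jump_min
            if jj >= 0:
                if H[i, jj] > rmax:
                    rmax = H[i, jj]
                J[i, j] = rmax + jump
            s = match if q[i - 1] == r[j - 1] else mismatch
            best = H[i - 1, j - 1] + s
            e = H[i - 1, j] + open_ext
            if E[i - 1, j] + ext > e:
                e = E[i - 1, j] + ext
            E[i, j] = e
            f = H[i, j - 1] + open_ext
            if F[i, j - 1] + ext > f:
                f = F[i, j - 1] + ext
            F[i, j] = f
            if e > best:
                best = e
            if f > best:
                best = f
            if J[i, j] > best:
                best = J[i, j]
            H[i, j] = best
    return H, E, F, J


def _traceback(q, r, H, E, F, J, params: ScoringParams) -> tuple[int, list, int]:
    m, n = len(q), len(r)
    open_ext = params.gap_open + params.gap_extend
    # best end column in the final row (free reference suffix); leftmost on ties
    jbest = int(np.argmax(H[m, :]))
    score = int(H[m, jbest])
    ops: list[str] = []
    i, j = m, jbest
    state = "H"
    while i > 0 or (state in ("F", "J")):
        if state == "H":
            if i == 0:
                break
            sub = params.match if q[i - 1] == r[j - 1] else params.mismatch
            # tie order: diagonal, long deletion, deletion, insertion
            if j > 0 and H[i, j] == H[i - 1, j - 1] + sub:
                ops.append("M")
                i -= 1
                j -= 1
            elif H[i, j] == J[i, j]:
                state = "J"
            elif H[i, j] == F[i, j]:
                state = "F"
            elif H[i, j] == E[i, j]:
                state = "E"
            else:  # pragma: no cover - matrix inconsistency
                raise RuntimeError("traceback failed")
        elif state == "E":
            ops.append("I")
            if E[i, j] == H[i - 1, j] + open_ext:
                state = "H"
            i -= 1
        elif state == "F":
            ops.append("D")
            if F[i, j] == H[i, j - 1] + open_ext:
                state = "H"
            j -= 1
        else:  # J: one flat-cost jump of length >= jump_min
            target = J[i, j] - params.long_del
            jj = -1
            for cand in range(0, j - params.long_del_min + 1):
                if H[i, cand] == target:
                    jj = cand
                    break
            if jj < 0:  # pragma: no cover
                raise RuntimeError("long-deletion traceback failed")
            ops.extend("D" * (j - jj))
            j = jj
            state = "H"
    ops.reverse()
    merged: list[tuple[str, int]] = []
    for op in ops:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + 1)
        else:
            merged.append((op, 1))
    return score, merged, j


def align_read(
    read: str, site: TargetSite, params: ScoringParams | None = None
) -> AmpliconAlignment | None:
    """Align one read (given in amplicon-forward orientation) to a site.

    Returns ``None`` when the best score falls below
    ``min_score_frac * match * len(read)`` (unmapped).
    """
    params = params or ScoringParams()
    if not read:
        return None
    ref = site.amplicon_seq
    # fast path: exact substring
    p = ref.find(read)
    if p >= 0:
        return AmpliconAlignment(
            site.site_id, read, p, [("M", len(read))], params.match * len(read)
        )
    q, r = _encode(read), _encode(ref)
    H, E, F, J = _fill_matrices(
        q,
        r,
        params.match,
        params.mismatch,
        params.gap_open + params.gap_extend,
        params.gap_extend,
        params.long_del,
        params.long_del_min,
    )
    score, ops, ref_start = _traceback(read, ref, H, E, F, J, params)
    if score < params.min_score_frac * params.match * len(read):
        return None
    return AmpliconAlignment(site.site_id, read, ref_start, ops, score)


# ---------------------------------------------------------------------------
# indel extraction and normalization


def left_align_deletion(ref: str, pos: int, length: int) -> tuple[int, str]:
    """Shift a deletion to its leftmost equivalent placement."""
    while pos > 0 and ref[pos - 1] == ref[pos + length - 1]:
        pos -= 1
    return pos, ref[pos : pos + length]


def left_align_insertion(ref: str, pos: int, seq: str) -> tuple[int, str]:
    """Shift an insertion to its leftmost equivalent placement."""
    while pos > 0 and seq and seq[-1] == ref[pos - 1]:
        seq = ref[pos - 1] + seq[:-1]
        pos -= 1
    return pos, seq


def extract_indels(
    alignment: AmpliconAlignment,
    site: TargetSite,
    window: int = 20,
    pair_id: str = "",
) -> list[RawIndelObservation]:
    """Emit left-aligned indel observations overlapping the cut-site window.

    Alignments that do not fully span ``cut_pos +/- window`` return an empty
    list; callers exclude such reads from the site denominator.
    """
    lo, hi = site.cut_pos - window, site.cut_pos + window
    if not alignment.spans(lo, hi):
        return []
    ref = site.amplicon_seq
    out = []
    rpos = alignment.ref_start
    qpos = 0
    for op, n in alignment.ops:
        if op == "M":
            rpos += n
            qpos += n
        elif op == "D":
            pos, seq = left_align_deletion(ref, rpos, n)
            if pos < hi and pos + n > lo:
                out.append(
                    RawIndelObservation(site.site_id, pos, "del", n, seq, pair_id)
                )
            rpos += n
        else:  # I
            ins = alignment.query[qpos : qpos + n]
            pos, seq = left_align_insertion(ref, rpos, ins)
            if lo <= pos <= hi:
                out.append(
                    RawIndelObservation(site.site_id, pos, "ins", n, seq, pair_id)
                )
            qpos += n
    return out


# ---------------------------------------------------------------------------
# read assignment and pairing


@dataclass
class OrientedPair:
    """A read pair assigned to one amplicon, both mates in forward orientation."""

    pair_id: str
    site_id: str
    fwd1: str
    fwd2: str


@dataclass
class PairingResult:
    pairs_by_site: dict[str, list[OrientedPair]]
    n_pairs: int
    n_unpaired: int

    @property
    def unpaired_fraction(self) -> float:
        return self.n_unpaired / self.n_pairs if self.n_pairs else 0.0


def _best_site(
    seq: str,
    panel: list[TargetSite],
    cache: dict[str, tuple[int, str, int] | None],
    max_dist: int,
    hint: int | None = None,
) -> tuple[int, str, int] | None:
    """Best (site index, orientation, distance) for one mate, or None.
    ``hint`` (e.g. the mate's assignment) is probed first.

    Whole-read edit distance misses reads spanning deletions larger than
    the distance cap (a deletion costs its full length), so unassigned
    reads fall back to probing in thirds: a read whose start/middle/end
    segments agree on one amplicon is assigned to it, while chimeric reads
    (segments from different amplicons, e.g. unanticipated fusion
    junctions) stay unassigned.
    """
    hit = cache.get(seq)
    if hit is not None or seq in cache:
        return hit
    rc = revcomp(seq)
    # a hit this close is unambiguous: references differ from each other by
    # far more than a read's expected error count (even junction references
    # sharing an amplicon prefix diverge by the whole opposite flank), so
    # scanning the remaining panel cannot change the assignment
    accept = 3
    best = None
    order = range(len(panel))
    if hint is not None:
        order = [hint] + [i for i in range(len(panel)) if i != hint]
    for idx in order:
        site = panel[idx]
        for orient, s in (("F", seq), ("R", rc)):
            k = max_dist if best is None else best[2] - 1
            if k < 0:
                continue  # an exact hit cannot be improved
            res = edlib.align(s, site.amplicon_seq, mode="HW", task="distance", k=k)
            d = res["editDistance"]
            if d != -1 and (best is None or d < best[2]):
                best = (idx, orient, d)
        if best is not None and best[2] <= accept:
            break
    if best is None and len(seq) >= 150:
        best = _probe_site(seq, rc, panel)
    cache[seq] = best
    return best


def _probe_site(
    seq: str, rc: str, panel: list[TargetSite]
) -> tuple[int, str, int] | None:
    third = len(seq) // 3
    probes = [(0, third), (third, 2 * third), (2 * third, len(seq))]
    hits: list[tuple[int, str, int]] = []
    for lo, hi in probes:
        k = max(5, int(0.2 * (hi - lo)))
        probe_best = None
        for idx, site in enumerate(panel):
            for orient, s in (("F", seq[lo:hi]), ("R", rc[len(seq) - hi : len(seq) - lo])):
                res = edlib.align(s, site.amplicon_seq, mode="HW", task="distance", k=k)
                d = res["editDistance"]
                if d != -1 and (probe_best is None or d < probe_best[2]):
                    probe_best = (idx, orient, d)
        if probe_best is not None:
            hits.append(probe_best)
    if len(hits) < 2:
        return None
    if len({(idx, orient) for idx, orient, _d in hits}) != 1:
        return None  # chimeric: segments from different amplicons/strands
    idx, orient, _ = hits[0]
    return (idx, orient, sum(d for _i, _o, d in hits))


def assign_and_pair(
    read_pairs: list[tuple[str, str, str]],
    panel: list[TargetSite],
    max_dist_frac: float = 0.25,
) -> PairingResult:
    """Assign mates to amplicons and keep properly paired reads only.

    ``read_pairs`` is a list of (pair_id, read1, read2). A pair is properly
    paired when both mates hit the same amplicon in opposite orientations;
    anything else (discordant amplicons, same orientation, an unassignable
    mate) is counted as unpaired and excluded downstream.
    """
    if not panel:
        raise ValueError("panel must be non-empty")
    if not read_pairs:
        logger.warning("assign_and_pair: empty read set")
        return PairingResult({}, 0, 0)
    cache: dict[str, tuple[int, str, int] | None] = {}
    by_site: dict[str, list[OrientedPair]] = {s.site_id: [] for s in panel}
    n_unpaired = 0
    for pair_id, r1, r2 in read_pairs:
        a1 = _best_site(r1, panel, cache, int(max_dist_frac * len(r1)))
        hint = a1[0] if a1 is not None else None
        a2 = _best_site(r2, panel, cache, int(max_dist_frac * len(r2)), hint=hint)
        if (
            a1 is None
            or a2 is None
            or a1[0] != a2[0]
            or a1[1] == a2[1]  # FR orientation required
        ):
            n_unpaired += 1
            continue
        site = panel[a1[0]]
        fwd1 = r1 if a1[1] == "F" else revcomp(r1)
        fwd2 = r2 if a2[1] == "F" else revcomp(r2)
        by_site[site.site_id].append(OrientedPair(pair_id, site.site_id, fwd1, fwd2))
    return PairingResult(by_site, len(read_pairs), n_unpaired)


# ---------------------------------------------------------------------------
# per-site read processing (clustered alignment driver)


@dataclass
class SiteObservations:
    """Pair-level indel observations at one site.

    ``per_pair`` maps pair_id -> set of indel identities; pairs present as
    keys span the counting window (possibly with an empty set = wild-type).
    """

    site_id: str
    per_pair: dict[str, frozenset]
    observations: list[RawIndelObservation]

    @property
    def spanning_pairs(self) -> int:
        return len(self.per_pair)


def score_from_ops(
    query: str,
    ref: str,
    ref_start: int,
    ops: list[tuple[str, int]],
    params: ScoringParams,
) -> int:
    """Score an alignment path under the declared scoring scheme."""
    score = 0
    rpos, qpos = ref_start, 0
    for op, n in ops:
        if op == "M":
            for k in range(n):
                score += (
                    params.match
                    if query[qpos + k] == ref[rpos + k]
                    else params.mismatch
                )
            rpos += n
            qpos += n
        elif op == "I":
            score += params.gap_open + n * params.gap_extend
            qpos += n
        else:
            if n >= params.long_del_min:
                score += max(params.long_del, params.gap_open + n * params.gap_extend)
            else:
                score += params.gap_open + n * params.gap_extend
            rpos += n
    return score


def _cluster_alignment(
    seq: str,
    reps: list[tuple[str, AmpliconAlignment]],
    site: TargetSite,
    params: ScoringParams,
    allow_reuse: bool,
) -> AmpliconAlignment | None:
    """Align a read, reusing the indel structure of a substitution-equivalent
    representative when permitted.

    Abundant distinct sequences (error-free haplotype reads) always get the
    full dynamic program and become representatives. A rare sequence
    differing from a representative only by base substitutions (edlib
    global CIGAR without I/D) inherits the best-scoring representative's op
    structure, so the full DP runs once per distinct indel structure rather
    than once per distinct error-bearing read.
    """
    best: AmpliconAlignment | None = None
    if allow_reuse:
        for rep_seq, rep_aln in reps:
            if len(rep_seq) != len(seq):
                continue
            res = edlib.align(seq, rep_seq, mode="NW", task="path", k=12)
            if res["editDistance"] == -1:
                continue
            cigar = res["cigar"] or ""
            if "I" in cigar or "D" in cigar:
                continue
            score = score_from_ops(
                seq, site.amplicon_seq, rep_aln.ref_start, rep_aln.ops, params
            )
            if best is None or score > best.score:
                best = AmpliconAlignment(
                    rep_aln.site_id, seq, rep_aln.ref_start, list(rep_aln.ops), score
                )
        if best is not None:
            return best
    aln = align_read(seq, site, params)
    if aln is not None and len(reps) < 64 and not allow_reuse:
        reps.append((seq, aln))
    return aln


def collect_site_observations(
    site: TargetSite,
    pairs: list[OrientedPair],
    params: ScoringParams | None = None,
    window: int = 20,
    rep_min_count: int = 3,
) -> SiteObservations:
    """Align all pairs at a site and collect pair-deduplicated observations.

    Each pair contributes once: observations from its two mates are merged
    by exact indel identity. A pair enters the denominator when at least one
    mate's alignment spans the cut-site window. Distinct sequences seen at
    least ``rep_min_count`` times are aligned in full and anchor the
    substitution-equivalence clusters that rarer (error-bearing) reads
    reuse.
    """
    params = params or ScoringParams()
    lo, hi = site.cut_pos - window, site.cut_pos + window
    distinct: Counter[str] = Counter()
    for p in pairs:
        distinct[p.fwd1] += 1
        distinct[p.fwd2] += 1
    reps: list[tuple[str, AmpliconAlignment]] = []
    aln_cache: dict[str, AmpliconAlignment | None] = {}
    for seq, count in distinct.most_common():
        aln_cache[seq] = _cluster_alignment(
            seq, reps, site, params, allow_reuse=count < rep_min_count
        )

    per_pair: dict[str, frozenset] = {}
    observations: list[RawIndelObservation] = []
    for p in pairs:
        idents = set()
        spanning = False
        for seq in (p.fwd1, p.fwd2):
            aln = aln_cache[seq]
            if aln is None or aln.is_clipped():
                continue
            if aln.spans(lo, hi):
                spanning = True
            for obs in extract_indels(aln, site, window, p.pair_id):
                idents.add(obs.identity)
        if not spanning:
            continue
        per_pair[p.pair_id] = frozenset(idents)
        for site_id, pos, typ, length, seq in idents:
            observations.append(
                RawIndelObservation(site_id, pos, typ, length, seq, p.pair_id)
            )
    return SiteObservations(site.site_id, per_pair, observations)
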