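"""Screening for CRISPR-induced structural variants between cut sites.

Simultaneous double-strand breaks at two sgRNA sites can be repaired by
joining the wrong ends: an intra-chromosomal deletion when the sites share
a chromosome, or a derivative chromosome (translocation) when they do not.
Candidate junctions are enumerated directly from the target panel, and a
junction is confirmed when sequence reads align to the predicted fusion
reference with breakpoints at (or within a small tolerance of) the exact
cut positions — the hallmark of a Cas9-induced event.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

from .align import AmpliconAlignment, ScoringParams, align_read
from .panel import TargetSite

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FusionCandidate:
    """A possible fusion of two cut sites, in the A->B derivative orientation.

    The predicted junction joins A's amplicon prefix (up to A's cut) to B's
    amplicon suffix (from B's cut); the predicted breakpoint therefore sits
    at offset ``site_a.cut_pos`` of the junction sequence.
    """

    site_a: TargetSite
    site_b: TargetSite

    def __post_init__(self) -> None:
        if self.site_a.site_id == self.site_b.site_id:
            raise ValueError("fusion candidate requires two distinct sites")

    @property
    def same_chrom(self) -> bool:
        return self.site_a.chrom == self.site_b.chrom

    @property
    def predicted_junction_seq(self) -> str:
        return (
            self.site_a.amplicon_seq[: self.site_a.cut_pos]
            + self.site_b.amplicon_seq[self.site_b.cut_pos :]
        )

    @property
    def predicted_deletion_span(self) -> int | None:
        if not self.same_chrom:
            return None
        if self.site_a.genomic_cut is None or self.site_b.genomic_cut is None:
            return None
        return abs(self.site_b.genomic_cut - self.site_a.genomic_cut)

    @property
    def label(self) -> str:
        return f"{self.site_a.site_id}--{self.site_b.site_id}"

    def as_pseudosite(self) -> TargetSite:
        """The junction reference as a pseudo target site (cut = breakpoint).

        Guide fields are inherited from site A purely to satisfy the
        schema; only the amplicon sequence and cut position are meaningful.
        """
        seq = self.predicted_junction_seq
        site = object.__new__(TargetSite)
        object.__setattr__(site, "site_id", self.label)
        object.__setattr__(site, "chrom", f"{self.site_a.chrom}|{self.site_b.chrom}")
        object.__setattr__(site, "amplicon_seq", seq)
        object.__setattr__(site, "protospacer", self.site_a.protospacer)
        object.__setattr__(site, "pam", self.site_a.pam)
        object.__setattr__(site, "strand", self.site_a.strand)
        object.__setattr__(site, "cut_pos", self.site_a.cut_pos)
        object.__setattr__(site, "gene", self.label)
        object.__setattr__(site, "genomic_cut", None)
        return site


def enumerate_intrachrom_fusions(panel: list[TargetSite]) -> list[FusionCandidate]:
    """All unordered same-chromosome site pairs (head-to-tail deletion joins).

    The count equals the sum of C(n_c, 2) over chromosomes c.
    """
    out = []
    by_chrom: dict[str, list[TargetSite]] = {}
    for s in panel:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom in sorted(by_chrom):
        for a, b in itertools.combinations(by_chrom[chrom], 2):
            out.append(FusionCandidate(a, b))
    return out


def enumerate_transloc_candidates(panel: list[TargetSite]) -> list[FusionCandidate]:
    """All cross-chromosome site pairs, in both derivative orientations."""
    out = []
    for a, b in itertools.combinations(panel, 2):
        if a.chrom == b.chrom:
            continue
        out.append(FusionCandidate(a, b))
        out.append(FusionCandidate(b, a))
    return out


@dataclass
class RearrangementCall:
    candidate: FusionCandidate
    support: int
    breakpoint_offset_a: int
    breakpoint_offset_b: int
    junction_indel: tuple[str, int] | None  # ("del"|"ins", length) at the seam
    junction_class: str | None = None       # set by classify_rearrangements

    @property
    def confirmed(self) -> bool:
        return self.support > 0


def _seam_indel(
    aln: AmpliconAlignment, seam: int, tol: int
) -> tuple[int, int, tuple[str, int] | None] | None:
    """Breakpoint offsets and seam indel for one junction alignment.

    Returns (offset_a, offset_b, indel) or None when an indel op near the
    seam exceeds the tolerance (the read does not support a breakpoint at
    the cut sites).
    """
    rpos = aln.ref_start
    offset_a = offset_b = 0
    indel = None
    for op, n in aln.ops:
        if op == "M":
            rpos += n
            continue
        if op == "D":
            lo, hi = rpos, rpos + n
            rpos += n
        else:
            lo = hi = rpos
        near = lo <= seam + tol and hi >= seam - tol
        if not near:
            # an indel elsewhere on the junction amplicon (e.g. residual
            # target-site editing) does not bear on the breakpoint
            continue
        if op == "D":
            oa = min(lo - seam, 0)
            ob = max(hi - seam, 0)
        else:
            oa = ob = lo - seam
        if abs(oa) > tol or abs(ob) > tol or n > 2 * tol:
            return None
        offset_a, offset_b = oa, ob
        indel = (("del" if op == "D" else "ins"), n)
    return offset_a, offset_b, indel


def detect_junction(
    sequences: list[str],
    candidate: FusionCandidate,
    tol: int = 10,
    params: ScoringParams | None = None,
    min_flank: int = 30,
) -> RearrangementCall | None:
    """Confirm a fusion candidate from reads or an assembled sequence.

    Each sequence is aligned against the predicted junction reference; a
    sequence supports the call when its alignment spans the seam with at
    least ``min_flank`` aligned bases on both sides and any seam-local
    indel keeps both breakpoint offsets within ``tol`` bp (NHEJ junction
    resection). Returns ``None`` when no sequence supports the junction.
    """
    params = params or ScoringParams()
    pseudo = candidate.as_pseudosite()
    seam = candidate.site_a.cut_pos
    support = 0
    offsets: tuple[int, int] = (0, 0)
    indel: tuple[str, int] | None = None
    for seq in sequences:
        aln = align_read(seq, pseudo, params)
        if aln is None:
            continue
        if not aln.spans(max(0, seam - min_flank), seam + min_flank):
            continue
        res = _seam_indel(aln, seam, tol)
        if res is None:
            continue
        oa, ob, ind = res
        if support == 0 or ind is not None:
            offsets = (oa, ob)
            if ind is not None:
                indel = ind
        support += 1
    if support == 0:
        return None
    return RearrangementCall(candidate, support, offsets[0], offsets[1], indel)


def classify_rearrangements(
    calls: list[RearrangementCall],
) -> list[RearrangementCall]:
    """Classify confirmed calls from one sample.

    Same-chromosome junctions are intra-chromosomal deletions. A
    cross-chromosome pair with both derivative junctions detected is a
    reciprocal translocation; a single derivative is non-reciprocal.
    """
    pairs: dict[frozenset, list[RearrangementCall]] = {}
    for call in calls:
        key = frozenset((call.candidate.site_a.site_id, call.candidate.site_b.site_id))
        pairs.setdefault(key, []).append(call)
    for group in pairs.values():
        for call in group:
            if call.candidate.same_chrom:
                call.junction_class = "intra_deletion"
            elif len(group) >= 2:
                call.junction_class = "translocation_reciprocal"
            else:
                call.junction_class = "translocation_nonreciprocal"
    return calls


def predicted_deletion_size(
    site_a: TargetSite, site_b: TargetSite, genomic_cuts: dict[str, int] | None = None
) -> int:
    """Genomic span removed by an intra-chromosomal deletion between two cuts."""
    if site_a.chrom != site_b.chrom:
        raise ValueError(
            f"{site_a.site_id} and {site_b.site_id} are on different chromosomes"
        )
    cuts = genomic_cuts or {}
    ca = cuts.get(site_a.site_id, site_a.genomic_cut)
    cb = cuts.get(site_b.site_id, site_b.genomic_cut)
    if ca is None or cb is None:
        raise ValueError("genomic cut coordinates required for both sites")
    span = abs(cb - ca)
    if span == 0:
        warnings.warn("degenerate deletion of size 0 (identical cut coordinates)", stacklevel=2)
    return span


def screen_sample(
    reads_by_junction: dict[str, list[str]],
    candidates: list[FusionCandidate],
    tol: int = 10,
    params: ScoringParams | None = None,
) -> list[RearrangementCall]:
    """Detect and classify junctions for one sample.

    ``reads_by_junction`` maps a candidate label to the (forward-oriented)
    sequences assigned to its predicted junction reference.
    """
    calls = []
    for cand in candidates:
        seqs = reads_by_junction.get(cand.label, [])
        if not seqs:
            continue
        call = detect_junction(seqs, cand, tol=tol, params=params)
        if call is not None:
            calls.append(call)
    return classify_rearrangements(calls)
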