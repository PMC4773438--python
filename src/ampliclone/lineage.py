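"""Clonal lineage tracking with CRISPR indel signatures.

Because Cas9 exposure was transient, the exact set of indels a founder
cell acquired acts as a heritable clonal barcode: independent tumours are
distinguished by (i) which genes are hit and (ii) the exact indel
identities (position, type, length, sequence) at each site, and a
metastasis carries its primary's signature unchanged. This module
formalizes the comparison: Jaccard distances between marker sets,
single-linkage clustering into independent primaries (with detection of
mixed biopsies), and nearest-signature assignment of metastases to their
tumour of origin.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .calling import SiteAlleleTable

logger = logging.getLogger(__name__)

Marker = tuple[str, tuple]


@dataclass(frozen=True)
class CloneSignature:
    """The set of (site, exact indel identity) markers of one sample."""

    sample_id: str
    markers: frozenset[Marker]


def build_signature(
    tables: dict[str, SiteAlleleTable],
    sample_id: str,
    relaxed: bool = False,
) -> CloneSignature:
    """Signature from filtered per-site allele tables.

    Marker identity is exact on (position, type, length, sequence); with
    ``relaxed=True`` the inserted/deleted sequence is ignored (position,
    type and length only), a mode for noisier callers.
    """
    markers = set()
    for site_id, table in tables.items():
        for allele, _support, _mrf in table.alleles:
            ident = (
                (allele.pos, allele.type, allele.length)
                if relaxed
                else allele.identity
            )
            markers.add((site_id, ident))
    return CloneSignature(sample_id, frozenset(markers))


def signature_distance(a: CloneSignature, b: CloneSignature) -> float:
    """Jaccard distance between marker sets; two empty signatures are
    maximally distant (with a warning) since they carry no evidence."""
    if not a.markers and not b.markers:
        warnings.warn("comparing two empty signatures", stacklevel=2)
        return 1.0
    inter = len(a.markers & b.markers)
    union = len(a.markers | b.markers)
    return 1.0 - inter / union


def shared_markers(a: CloneSignature, b: CloneSignature) -> int:
    return len(a.markers & b.markers)


@dataclass
class PrimaryDeconvolution:
    """Clustering of sample signatures into independent primary tumours."""

    clusters: list[list[str]]                 # sample ids per cluster
    mixed: dict[str, list[int]]               # mixed sample -> cluster indices
    mixed_components: dict[str, dict[int, frozenset]]  # markers per contributing cluster
    linkage_matrix: np.ndarray | None
    sample_order: list[str]


def deconvolve_primaries(
    signatures: list[CloneSignature],
    min_shared: int = 2,
    max_intra_distance: float = 0.3,
) -> PrimaryDeconvolution:
    """Cluster signatures into independent primaries; flag mixed samples.

    Single-linkage clustering at ``max_intra_distance`` (Jaccard) defines
    preliminary clusters. Samples whose markers are shared (at least
    ``min_shared`` each) with two or more clusters are provisional
    mixtures; the remaining pure samples are re-clustered, and the final
    mixed calls are made against these pure clusters only, so a mixture
    never contaminates the test for other samples. When single-cell-clone
    signatures are among the input they anchor the constituent clusters,
    and a mixed sample's markers are partitioned over them
    (``mixed_components``).

    The output is invariant to input order (samples are sorted internally).
    """
    if not signatures:
        raise ValueError("need at least one signature")
    sigs = sorted(signatures, key=lambda s: s.sample_id)
    ids = [s.sample_id for s in sigs]
    n = len(sigs)
    if n == 1:
        return PrimaryDeconvolution([[ids[0]]], {}, {}, None, ids)

    def _cluster(indices: list[int]) -> list[list[int]]:
        if len(indices) == 1:
            return [list(indices)]
        k = len(indices)
        dist = np.zeros((k, k))
        for a in range(k):
            for b in range(a + 1, k):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    d = signature_distance(sigs[indices[a]], sigs[indices[b]])
                dist[a, b] = dist[b, a] = d
        lm = linkage(squareform(dist, checks=False), method="single")
        labels = fcluster(lm, t=max_intra_distance, criterion="distance")
        groups: dict[int, list[int]] = {}
        for a, lab in enumerate(labels):
            groups.setdefault(int(lab), []).append(indices[a])
        return sorted(groups.values(), key=lambda g: min(ids[i] for i in g))

    def _hits(i: int, clusters: list[list[int]]) -> dict[int, frozenset]:
        """Clusters that each explain >= min_shared markers of sample i not
        already explained by a larger-contributing cluster. Two or more such
        clusters mean the sample's markers genuinely decompose into several
        primaries (a pure sample overlapping a mixture's hybrid cluster
        contributes no novel markers and is not counted twice)."""
        comps: dict[int, frozenset] = {}
        for ci, group in enumerate(clusters):
            union: set = set()
            for j in group:
                if j != i:
                    union |= sigs[j].markers
            inter = sigs[i].markers & union
            if len(inter) >= min_shared:
                comps[ci] = frozenset(inter)
        selected: dict[int, frozenset] = {}
        explained: set = set()
        for ci in sorted(comps, key=lambda c: (-len(comps[c]), c)):
            if len(comps[ci] - explained) >= min_shared:
                selected[ci] = comps[ci]
                explained |= comps[ci]
        return selected

    # pass 1: provisional mixtures against clusters over all samples
    prelim_clusters = _cluster(list(range(n)))
    provisional = {
        i for i in range(n) if len(_hits(i, prelim_clusters)) >= 2
    }
    pure = [i for i in range(n) if i not in provisional]
    if not pure or not provisional:
        final_clusters = prelim_clusters
    else:
        final_clusters = _cluster(pure)

    # pass 2: final mixed calls against pure clusters only
    mixed: dict[str, list[int]] = {}
    mixed_components: dict[str, dict[int, frozenset]] = {}
    for i in range(n):
        comps = _hits(i, final_clusters)
        if len(comps) >= 2:
            mixed[ids[i]] = sorted(comps)
            mixed_components[ids[i]] = comps

    # cleared provisional samples rejoin the best-matching cluster
    placed: dict[int, list[int]] = {ci: list(g) for ci, g in enumerate(final_clusters)}
    for i in range(n):
        if ids[i] in mixed or any(i in g for g in final_clusters):
            continue
        comps = _hits(i, final_clusters)
        if comps:
            best = max(comps, key=lambda ci: (len(comps[ci]), -ci))
            placed[best].append(i)
        else:
            placed[len(placed)] = [i]

    clusters = sorted(
        (sorted(ids[i] for i in g if ids[i] not in mixed) for g in placed.values()),
        key=lambda c: (c[0] if c else ""),
    )
    clusters = [c for c in clusters if c]

    # full-input dendrogram for export
    dist = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                dist[a, b] = dist[b, a] = signature_distance(sigs[a], sigs[b])
    lm = linkage(squareform(dist, checks=False), method="single")
    return PrimaryDeconvolution(clusters, mixed, mixed_components, lm, ids)


@dataclass(frozen=True)
class OriginAssignment:
    """Assignment of one metastasis to its tumour of origin."""

    met_id: str
    assigned_primary: str  # primary sample_id or "ambiguous"
    shared_markers: int
    margin: int            # best minus second-best shared-marker count


def assign_metastases(
    met_signatures: list[CloneSignature],
    primary_signatures: list[CloneSignature],
    min_shared: int = 2,
    min_margin: int = 1,
) -> list[OriginAssignment]:
    """Assign each metastasis to the primary sharing the most exact markers.

    A call requires at least ``min_shared`` shared markers and a margin of
    at least ``min_margin`` over the runner-up; otherwise the nodule is
    reported ambiguous.
    """
    if not primary_signatures:
        raise ValueError("need at least one primary signature")
    primaries = sorted(primary_signatures, key=lambda s: s.sample_id)
    out = []
    for met in met_signatures:
        counts = [(shared_markers(met, p), p.sample_id) for p in primaries]
        counts.sort(key=lambda t: (-t[0], t[1]))
        best_n, best_id = counts[0]
        second_n = counts[1][0] if len(counts) > 1 else 0
        margin = best_n - second_n
        if best_n >= min_shared and margin >= min_margin:
            out.append(OriginAssignment(met.sample_id, best_id, best_n, margin))
        else:
            out.append(OriginAssignment(met.sample_id, "ambiguous", best_n, margin))
    return out


def origin_fractions(assignments: list[OriginAssignment]) -> dict[str, float]:
    """Fraction of nodules per assigned primary (ambiguous kept separate)."""
    if not assignments:
        return {}
    counts: dict[str, int] = {}
    for a in assignments:
        counts[a.assigned_primary] = counts.get(a.assigned_primary, 0) + 1
    return {k: v / len(assignments) for k, v in sorted(counts.items())}


def dendrogram_newick(result: PrimaryDeconvolution) -> str:
    """Newick export of the single-linkage dendrogram."""
    if result.linkage_matrix is None:
        return f"({result.sample_order[0]});"
    from skbio import TreeNode

    tree = TreeNode.from_linkage_matrix(result.linkage_matrix, result.sample_order)
    return str(tree)


def signature_frame(signatures: list[CloneSignature]):
    """Signatures as a flat table (sample, site, pos, type, len, seq)."""
    import pandas as pd

    rows = []
    for sig in signatures:
        for site_id, ident in sorted(sig.markers):
            pos, typ, length, seq = ident[0], ident[1], ident[2], (
                ident[3] if len(ident) > 3 else ""
            )
            rows.append(
                {
                    "sample_id": sig.sample_id,
                    "site_id": site_id,
                    "pos": pos,
                    "type": typ,
                    "length": length,
                    "seq": seq,
                }
            )
    return pd.DataFrame(
        rows, columns=["sample_id", "site_id", "pos", "type", "length", "seq"]
    )
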