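"""Zygosity classification and ploidy-constrained allele-copy assignment.

Complete inactivation of a target gene means no chromosome retains the
wild-type sequence; partial inactivation means at least one wild-type copy
survives. These calls are only meaningful in pure cell populations (cell
lines, single-cell clones) — in tissue the stromal wild-type admixture
makes the wild-type read fraction uninterpretable, so tissue samples
receive ``mutated_zygosity_indeterminate`` at best.

With a karyotype-derived copy number k, observed allele frequencies can be
assigned to integer chromosome copies by exhaustively searching the
compositions of k over the observed alleles for the least-squares fit
(e.g. wild-type plus three indels over the seven copies of a chromosome).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

from .calling import SiteAlleleTable

logger = logging.getLogger(__name__)

SITE_STATUSES = (
    "complete",
    "partial",
    "unmutated",
    "mutated_zygosity_indeterminate",
    "no_data",
)

#: sample kinds that are pure enough for complete/partial calls
_CULTURE_KINDS = ("cell_line", "single_cell_clone")


@dataclass(frozen=True)
class SiteStatus:
    site_id: str
    sample_kind: str
    status: str
    cumulative_mrf: float
    wt_fraction: float


def classify_site(
    table: SiteAlleleTable, sample_kind: str, wt_epsilon: float = 0.01
) -> SiteStatus:
    """Classify target-gene inactivation at one site from a filtered table.

    ``wt_epsilon`` operationalizes "lack of wild-type sequence reads":
    at a 0.1% sequencing error rate a strictly zero wild-type count is not
    attainable, so complete inactivation is called when the wild-type
    fraction does not exceed ``wt_epsilon``.
    """
    if table.total_spanning_reads == 0:
        return SiteStatus(table.site_id, sample_kind, "no_data", float("nan"), float("nan"))
    mutated = len(table.alleles) > 0
    wt_frac = table.wt_fraction
    if sample_kind in _CULTURE_KINDS:
        if not mutated:
            status = "unmutated"
        elif wt_frac <= wt_epsilon:
            status = "complete"
        else:
            status = "partial"
    else:
        status = "mutated_zygosity_indeterminate" if mutated else "unmutated"
    return SiteStatus(table.site_id, sample_kind, status, table.cumulative_mrf, wt_frac)


def cohort_zygosity_fractions(
    statuses: list[SiteStatus],
) -> tuple[float, float]:
    """(complete, partial) fractions over mutated culture-sample sites."""
    complete = sum(1 for s in statuses if s.status == "complete")
    partial = sum(1 for s in statuses if s.status == "partial")
    total = complete + partial
    if total == 0:
        raise ValueError("no mutated sites with a zygosity call")
    return complete / total, partial / total


@dataclass
class AlleleCopyAssignment:
    """Integer copy counts explaining observed allele frequencies at ploidy k."""

    copy_number: int
    copies: dict[str, int]          # allele label (incl. "WT") -> copy count
    residual: float                 # sum of squared deviations from copies/k
    ambiguous: bool                 # >= 2 compositions tie at minimal residual
    feasible: bool = True           # False when more alleles than copies


def _compositions(total: int, parts: int):
    """All ways to write ``total`` as ``parts`` ordered non-negative integers."""
    for cuts in itertools.combinations(range(total + parts - 1), parts - 1):
        prev = -1
        comp = []
        for c in cuts:
            comp.append(c - prev - 1)
            prev = c
        comp.append(total + parts - 2 - prev)
        yield tuple(comp)


def assign_allele_copies(
    freqs: dict[str, float],
    copy_number: int,
    noise_floor: float = 0.01,
) -> AlleleCopyAssignment:
    """Least-squares assignment of allele frequencies to integer copies.

    ``freqs`` maps allele labels (including ``"WT"``) to observed read
    fractions summing to ~1. Searches all compositions of ``copy_number``
    over the alleles, minimizing ``sum((f_i - c_i / k)^2)``. Ties at the
    minimal residual are broken towards the assignment retaining the most
    wild-type copies (conservative about loss) and flagged ambiguous.
    When more alleles than copies are observed above the noise floor the
    result is flagged infeasible (subclonality, or a wrong karyotype).
    """
    if not 1 <= copy_number <= 12:
        raise ValueError("copy_number must be in [1, 12]")
    if any(f < 0 for f in freqs.values()):
        raise ValueError("frequencies must be non-negative")
    total = sum(freqs.values())
    if abs(total - 1.0) > 0.05:
        raise ValueError(f"frequencies must sum to ~1 (got {total:.3f})")

    labels = sorted(freqs, key=lambda l: (l != "WT", l))
    above_noise = [l for l in labels if l != "WT" and freqs[l] > noise_floor]
    wt_present = freqs.get("WT", 0.0) > noise_floor
    if len(above_noise) + int(wt_present) > copy_number:
        logger.warning(
            "more alleles (%d) than chromosome copies (%d): infeasible",
            len(above_noise) + int(wt_present),
            copy_number,
        )
        return AlleleCopyAssignment(copy_number, {}, float("inf"), False, feasible=False)

    fvec = [freqs[l] for l in labels]
    best: tuple[float, int, tuple[int, ...]] | None = None
    ambiguous = False
    for comp in _compositions(copy_number, len(labels)):
        resid = sum((f - c / copy_number) ** 2 for f, c in zip(fvec, comp))
        wt_copies = comp[labels.index("WT")] if "WT" in labels else 0
        key = (round(resid, 12), -wt_copies, comp)
        if best is None or key[0] < best[0]:
            best = key
            best_resid = resid
            ambiguous = False
        elif key[0] == best[0]:
            ambiguous = True
            if key < best:
                best = key
                best_resid = resid
    assert best is not None
    _qresid, _neg_wt, comp = best
    resid = best_resid
    return AlleleCopyAssignment(
        copy_number,
        dict(zip(labels, comp)),
        resid,
        ambiguous,
        feasible=True,
    )


def min_copies_at_editing(
    table: SiteAlleleTable, wt_epsilon: float = 0.01
) -> int:
    """Lower bound on the chromosome copy number at editing time.

    Every distinct surviving indel allele arose on a separate chromosome
    copy during transient Cas9 exposure, plus one copy if wild-type reads
    persist above ``wt_epsilon``; at least one copy always exists.
    """
    n = len(table.alleles)
    if table.total_spanning_reads and table.wt_fraction > wt_epsilon:
        n += 1
    return max(n, 1)
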