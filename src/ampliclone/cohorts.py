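"""Pre-configured synthetic study cohorts.

These builders fix the conditions of the emulated study: the 15-site
panel, six tumour-derived cell lines plus one tumour tissue (ploidy 2-7),
per-sgRNA delivery probability 0.8 with Brca2 excluded from viable tumour
clones (negative selection), structural variants in three tumours, and a
two-primary metastatic mouse for lineage tracking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panel import TargetSite, study_panel
from .simulate import (
    CloneTruth,
    IndelAllele,
    IndelModel,
    SampleTruth,
    SimConfig,
    metastasis_clone,
    sample_indel,
    simulate_clone,
    simulate_sample_reads,
)

#: per-sgRNA probability that a guide reaches and acts in the founder cell
P_DELIVERY = 0.8
#: probability that a delivered guide edits an individual chromosome copy
P_COPY_EDIT = 0.9
#: genes under negative selection: edited clones do not form tumours
SELECTION_BLOCKLIST = ("Brca2",)

#: per-tumour karyotypes (chromosome copy number; default 2 per chromosome).
#: Tu2 is the poly-/aneuploid cancer with seven copies of chromosome 6.
TUMOUR_PLOIDIES: dict[str, dict[str, int]] = {
    "Tu1": {},
    "Tu2": {"chr6": 7, "chr4": 4, "chr18": 3, "chr11": 3},
    "Tu3": {"chr4": 3},
    "Tu4": {},
    "Tu5": {"chr11": 4, "chr19": 3},
    "Tu6": {"chr6": 3, "chr17": 3},
    "Tu7": {},
}

#: structural variants carried by individual tumours
TUMOUR_REARRANGEMENTS: dict[str, list[tuple[str, str, str]]] = {
    "Tu2": [("Cdkn2b", "Apc", "translocation_reciprocal")],
    "Tu4": [("Cdkn2a-ex1b", "Cdkn2a-ex2", "intra_deletion")],
    "Tu5": [("Pten", "Arid1b", "translocation_nonreciprocal")],
}


def _full_ploidy(panel: list[TargetSite], overrides: dict[str, int]) -> dict[str, int]:
    ploidy = {s.chrom: 2 for s in panel}
    ploidy.update(overrides)
    return ploidy


@dataclass
class StudyCohort:
    panel: list[TargetSite]
    clones: dict[str, CloneTruth]
    samples: list[SampleTruth]
    config: SimConfig


def build_study_cohort(
    seed: int,
    coverage: int = 1000,
    model: IndelModel | None = None,
) -> StudyCohort:
    """The main cohort: Tu1-Tu6 cell lines, Tu7 tissue, one normal tissue."""
    panel = study_panel()
    model = model or IndelModel()
    rng = np.random.default_rng(seed)
    clones: dict[str, CloneTruth] = {}
    samples: list[SampleTruth] = []
    for tumour, overrides in TUMOUR_PLOIDIES.items():
        clone = simulate_clone(
            tumour,
            panel,
            _full_ploidy(panel, overrides),
            model,
            rng,
            p_delivery=P_DELIVERY,
            p_copy_edit=P_COPY_EDIT,
            blocked_genes=SELECTION_BLOCKLIST,
        )
        clone.rearrangements = list(TUMOUR_REARRANGEMENTS.get(tumour, []))
        clones[tumour] = clone
        if tumour == "Tu7":
            # tumour tissue: heavy stromal wild-type admixture
            samples.append(
                SampleTruth(f"{tumour}_Ti", "tumour_tissue", {tumour: 0.4}, 0.6)
            )
        else:
            samples.append(SampleTruth(tumour, "cell_line", {tumour: 1.0}, 0.0))
    samples.append(SampleTruth("PancTi", "normal", {}, 1.0))
    config = SimConfig(seed=int(rng.integers(2**31)), coverage_per_site=coverage)
    return StudyCohort(panel, clones, samples, config)


@dataclass
class LineageCohort:
    panel: list[TargetSite]
    clones: dict[str, CloneTruth]
    samples: list[SampleTruth]
    config: SimConfig
    truth_origin: dict[str, str]       # met sample -> true primary clone
    mixed_biopsies: tuple[str, ...]    # biopsies containing both primaries


def build_lineage_cohort(
    seed: int,
    coverage: int = 1000,
    n_sites: int = 6,
    n_biopsies: int = 8,
    n_clones_tu1: int = 3,
    n_clones_tu2: int = 3,
    mets: tuple[str, ...] = ("Tu1", "Tu1", "Tu1", "Tu1", "Tu1", "Tu2", "Tu2", "Tu2", "Tu2"),
    min_private_markers: int = 3,
) -> LineageCohort:
    """One mouse, two independent primaries sharing a tumour mass.

    Biopsy 1 is a mixture of both primaries; the remaining biopsies are
    pure Tu1 with stromal admixture. Single-cell clones from biopsy 1 and
    nine metastatic nodules (defaulting to a 5/4 Tu1/Tu2 split) complete
    the sample set. Primary clones are redrawn until each carries at least
    ``min_private_markers`` private markers, the regime in which indel
    barcodes are fully informative.
    """
    panel = study_panel()[:n_sites]
    model = IndelModel()
    rng = np.random.default_rng(seed)
    ploidy = _full_ploidy(panel, {})
    for _ in range(200):
        tu1 = simulate_clone("Tu1", panel, ploidy, model, rng, P_DELIVERY, P_COPY_EDIT)
        tu2 = simulate_clone("Tu2", panel, ploidy, model, rng, P_DELIVERY, P_COPY_EDIT)
        s1, s2 = tu1.signature(), tu2.signature()
        if len(s1 - s2) >= min_private_markers and len(s2 - s1) >= min_private_markers:
            break
    else:  # pragma: no cover
        raise RuntimeError("could not draw two sufficiently distinct clones")
    clones = {"Tu1": tu1, "Tu2": tu2}
    samples = [
        SampleTruth("Tu1", "cell_line", {"Tu1": 1.0}, 0.0),
        SampleTruth("Tu2", "cell_line", {"Tu2": 1.0}, 0.0),
        SampleTruth("biopsy_1", "tumour_tissue", {"Tu1": 0.55, "Tu2": 0.35}, 0.10),
    ]
    for i in range(2, n_biopsies + 1):
        samples.append(
            SampleTruth(f"biopsy_{i}", "tumour_tissue", {"Tu1": 0.9}, 0.10)
        )
    sc_idx = 0
    for parent, n in (("Tu1", n_clones_tu1), ("Tu2", n_clones_tu2)):
        for _ in range(n):
            sc_idx += 1
            samples.append(
                SampleTruth(f"sc_{sc_idx:02d}", "single_cell_clone", {parent: 1.0}, 0.0)
            )
    truth_origin = {}
    for i, parent in enumerate(mets, start=1):
        met_id = f"met_{i}"
        clones[met_id] = metastasis_clone(clones[parent], met_id)
        samples.append(
            SampleTruth(met_id, "metastasis", {met_id: 1.0}, 0.0, parent_primary=parent)
        )
        truth_origin[met_id] = parent
    config = SimConfig(seed=int(rng.integers(2**31)), coverage_per_site=coverage)
    return LineageCohort(panel, clones, samples, config, truth_origin, ("biopsy_1",))


def clone_with_composition(
    site: TargetSite,
    copy_number: int,
    n_alleles: int,
    composition: tuple[int, ...],
    rng: np.random.Generator,
    clone_id: str = "clone",
    model: IndelModel | None = None,
) -> CloneTruth:
    """A clone with a prescribed allele-copy composition at one site.

    ``composition`` gives copy counts (wt_copies, allele1, allele2, ...)
    summing to ``copy_number``; distinct alleles are drawn until their
    identities differ.
    """
    if sum(composition) != copy_number or len(composition) != n_alleles + 1:
        raise ValueError("composition must be (wt, a1, ..) summing to copy_number")
    model = model or IndelModel()
    alleles: list[IndelAllele] = []
    for _ in range(500):
        cand = sample_indel(model, site, rng)
        if all(cand.identity != a.identity for a in alleles):
            alleles.append(cand)
        if len(alleles) == n_alleles:
            break
    else:  # pragma: no cover
        raise RuntimeError("could not draw distinct alleles")
    slots: dict[tuple[str, int], IndelAllele | None] = {}
    c = 0
    for _ in range(composition[0]):
        slots[(site.site_id, c)] = None
        c += 1
    for allele, n in zip(alleles, composition[1:]):
        for _ in range(n):
            slots[(site.site_id, c)] = allele
            c += 1
    return CloneTruth(clone_id, {site.chrom: copy_number}, slots)
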