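"""End-to-end drivers: reads -> pairing -> alignment -> filtered allele tables."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .align import (
    OrientedPair,
    PairingResult,
    ScoringParams,
    assign_and_pair,
    collect_site_observations,
)
from .calling import FilterParams, SiteAlleleTable, filter_indels, pileup_site
from .panel import TargetSite
from .rearrange import FusionCandidate, RearrangementCall, screen_sample

logger = logging.getLogger(__name__)


@dataclass
class SampleCallResult:
    sample_id: str
    tables: dict[str, SiteAlleleTable]          # filtered, per site
    raw_tables: dict[str, SiteAlleleTable]      # pre-filter
    unpaired_fraction: float


def call_sample(
    sample_id: str,
    read_pairs: list[tuple[str, str, str]],
    panel: list[TargetSite],
    filter_params: FilterParams,
    scoring: ScoringParams | None = None,
    window: int = 20,
    extra_references: list[TargetSite] | None = None,
    pairing: PairingResult | None = None,
) -> SampleCallResult:
    """Run the per-sample calling pipeline.

    ``extra_references`` (e.g. predicted junction pseudo-sites) take part in
    read assignment so their reads are not forced onto target amplicons,
    but allele tables are only built for the panel proper. A precomputed
    ``pairing`` (over the same references) skips re-assignment.
    """
    scoring = scoring or ScoringParams()
    refs = list(panel) + list(extra_references or [])
    if pairing is None:
        pairing = assign_and_pair(read_pairs, refs)
    raw_tables: dict[str, SiteAlleleTable] = {}
    tables: dict[str, SiteAlleleTable] = {}
    for site in panel:
        pairs = pairing.pairs_by_site.get(site.site_id, [])
        obs = collect_site_observations(site, pairs, scoring, window)
        table = pileup_site(obs)
        raw_tables[site.site_id] = table
        tables[site.site_id] = filter_indels(table, filter_params)
    return SampleCallResult(
        sample_id, tables, raw_tables, pairing.unpaired_fraction
    )


def call_cohort(
    reads_by_sample: dict[str, list[tuple[str, str, str]]],
    panel: list[TargetSite],
    filter_params: FilterParams,
    scoring: ScoringParams | None = None,
    window: int = 20,
    extra_references: list[TargetSite] | None = None,
) -> dict[str, SampleCallResult]:
    return {
        sample_id: call_sample(
            sample_id, reads, panel, filter_params, scoring, window, extra_references
        )
        for sample_id, reads in reads_by_sample.items()
    }


def process_sample(
    sample_id: str,
    read_pairs: list[tuple[str, str, str]],
    panel: list[TargetSite],
    filter_params: FilterParams,
    candidates: list[FusionCandidate] | None = None,
    scoring: ScoringParams | None = None,
    window: int = 20,
    tol: int = 10,
) -> tuple[SampleCallResult, list[RearrangementCall]]:
    """Indel calling plus rearrangement screening with a single read assignment."""
    candidates = candidates or []
    pseudo = [c.as_pseudosite() for c in candidates]
    pairing = assign_and_pair(read_pairs, list(panel) + pseudo)
    result = call_sample(
        sample_id, read_pairs, panel, filter_params, scoring, window,
        extra_references=pseudo, pairing=pairing,
    )
    calls = screen_rearrangements(
        read_pairs, panel, candidates, tol=tol, scoring=scoring, pairing=pairing
    )
    return result, calls


def screen_rearrangements(
    read_pairs: list[tuple[str, str, str]],
    panel: list[TargetSite],
    candidates: list[FusionCandidate],
    tol: int = 10,
    scoring: ScoringParams | None = None,
    pairing: PairingResult | None = None,
) -> list[RearrangementCall]:
    """Assign reads across panel + junction references, then confirm junctions."""
    if pairing is None:
        pseudo = [c.as_pseudosite() for c in candidates]
        pairing = assign_and_pair(read_pairs, list(panel) + pseudo)
    reads_by_junction: dict[str, list[str]] = {}
    for cand in candidates:
        seqs = []
        for pair in pairing.pairs_by_site.get(cand.label, []):
            seqs.extend([pair.fwd1, pair.fwd2])
        reads_by_junction[cand.label] = seqs
    return screen_sample(reads_by_junction, candidates, tol=tol, params=scoring)
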