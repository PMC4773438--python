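"""Per-site allele tables, mutant-read frequencies and cohort summaries.

The mutant read frequency (MRF) of an allele is the fraction of mutant
reads among all reads spanning the target locus; the cumulative MRF sums
over every mutant allele at the locus. An indel call is only considered
true when supported by *more than* ``min_mutant_reads`` reads (strict
inequality) and when its MRF exceeds the sequencing-error floor.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, replace

import pandas as pd

from .align import RawIndelObservation, SiteObservations
from .panel import TargetSite
from .simulate import IndelAllele

logger = logging.getLogger(__name__)


@dataclass
class SiteAlleleTable:
    """Allele counts and MRFs at one target site in one sample.

    Invariants: ``wt_reads + sum(support) + unassigned == total_spanning_reads``
    and ``mrf_i == support_i / total_spanning_reads``. Counts are in units
    of read pairs (a properly paired fragment contributes once).
    """

    site_id: str
    total_spanning_reads: int
    alleles: list[tuple[IndelAllele, int, float]]  # (allele, support, mrf)
    wt_reads: int
    unassigned: int = 0

    @property
    def cumulative_mrf(self) -> float:
        return sum(mrf for _a, _s, mrf in self.alleles)

    @property
    def wt_fraction(self) -> float:
        if self.total_spanning_reads == 0:
            return float("nan")
        return self.wt_reads / self.total_spanning_reads

    def validate(self) -> None:
        total = self.wt_reads + self.unassigned + sum(s for _a, s, _m in self.alleles)
        if total != self.total_spanning_reads:
            raise ValueError(
                f"{self.site_id}: count conservation violated "
                f"({total} != {self.total_spanning_reads})"
            )
        for _a, s, m in self.alleles:
            if self.total_spanning_reads and not math.isclose(
                m, s / self.total_spanning_reads
            ):
                raise ValueError(f"{self.site_id}: inconsistent MRF")


@dataclass(frozen=True)
class FilterParams:
    """Support filter: keep alleles with support > min_mutant_reads (strict)
    and MRF > error_floor."""

    min_mutant_reads: int = 100
    error_floor: float = 0.005

    def __post_init__(self) -> None:
        if self.min_mutant_reads < 0:
            raise ValueError("min_mutant_reads must be >= 0")
        if not 0.0 <= self.error_floor < 1.0:
            raise ValueError("error_floor must be in [0, 1)")


def scaled_filter_params(coverage: int, error_floor: float = 0.005) -> FilterParams:
    """Support threshold scaled to desk-scale synthetic coverage.

    The documented default of 100 mutant reads assumes full MiSeq depth;
    for smaller simulated runs the threshold scales as
    ``max(10, 0.01 * coverage)``.
    """
    return FilterParams(max(10, int(0.01 * coverage)), error_floor)


def pileup_site(
    observations: list[RawIndelObservation] | SiteObservations,
    spanning_read_count: int | None = None,
    site: TargetSite | None = None,
) -> SiteAlleleTable:
    """Aggregate pair-level observations into a per-site allele table.

    Identical normalized indels merge into one allele with summed support;
    support counts distinct pairs, and each pair supports exactly one
    allele. Wild-type reads are spanning pairs carrying no windowed indel.
    The rare pair showing two or more distinct windowed indels (at the
    simulated error rates, an alignment artifact of an error-bearing read)
    is tallied as unassigned rather than invented as a composite allele.
    """
    if isinstance(observations, SiteObservations):
        site_id = observations.site_id
        spanning = observations.spanning_pairs
        obs = observations.observations
    else:
        if spanning_read_count is None:
            raise ValueError("spanning_read_count required with a raw observation list")
        site_id = site.site_id if site is not None else (
            observations[0].site_id if observations else "unknown"
        )
        spanning = spanning_read_count
        obs = observations
    if spanning < 0:
        raise ValueError("spanning_read_count must be >= 0")

    by_pair: dict[str, set[tuple]] = {}
    for o in obs:
        by_pair.setdefault(o.pair_id, set()).add((o.pos, o.type, o.length, o.seq))
    if len(by_pair) > spanning:
        raise ValueError(
            f"{site_id}: {len(by_pair)} mutant pairs exceed {spanning} spanning reads"
        )
    support: dict[tuple, int] = {}
    unassigned = 0
    for idents in by_pair.values():
        if len(idents) == 1:
            key = next(iter(idents))
            support[key] = support.get(key, 0) + 1
        else:
            unassigned += 1
    alleles = []
    for (pos, typ, length, seq), n in sorted(
        support.items(), key=lambda kv: (-kv[1], kv[0])
    ):
        alleles.append(
            (IndelAllele(pos, typ, length, seq), n, n / spanning if spanning else 0.0)
        )
    table = SiteAlleleTable(
        site_id=site_id,
        total_spanning_reads=spanning,
        alleles=alleles,
        wt_reads=spanning - len(by_pair),
        unassigned=unassigned,
    )
    table.validate()
    return table


def filter_indels(table: SiteAlleleTable, params: FilterParams) -> SiteAlleleTable:
    """Apply the support filter; removed support goes to an unassigned tally.

    Removed reads are *not* reassigned to wild-type: a filtered allele is
    unresolved, not evidence of an intact locus.
    """
    kept, dropped = [], 0
    for allele, support, mrf in table.alleles:
        if support > params.min_mutant_reads and mrf > params.error_floor:
            kept.append((allele, support, mrf))
        else:
            dropped += support
    out = replace(
        table, alleles=kept, unassigned=table.unassigned + dropped
    )
    out.validate()
    return out


# ---------------------------------------------------------------------------
# cohort-level summaries


def indel_catalogue(
    tables_by_sample: dict[str, dict[str, SiteAlleleTable]],
) -> pd.DataFrame:
    """Flat catalogue of filtered indel alleles across samples and sites."""
    rows = []
    for sample_id, tables in tables_by_sample.items():
        for site_id, table in tables.items():
            for allele, support, mrf in table.alleles:
                rows.append(
                    {
                        "sample_id": sample_id,
                        "site_id": site_id,
                        "type": allele.type,
                        "pos": allele.pos,
                        "length": allele.length,
                        "seq": allele.seq,
                        "support": support,
                        "mrf": mrf,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id", "site_id", "type", "pos", "length", "seq", "support", "mrf",
        ],
    )


def tables_to_frames(
    tables_by_sample: dict[str, dict[str, SiteAlleleTable]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(per-site denominators, allele catalogue) as flat frames."""
    site_rows = []
    for sample_id, tables in tables_by_sample.items():
        for site_id, t in tables.items():
            site_rows.append(
                {
                    "sample_id": sample_id,
                    "site_id": site_id,
                    "total_spanning_reads": t.total_spanning_reads,
                    "wt_reads": t.wt_reads,
                    "unassigned": t.unassigned,
                    "cumulative_mrf": t.cumulative_mrf,
                }
            )
    return pd.DataFrame(site_rows), indel_catalogue(tables_by_sample)


def frames_to_tables(
    site_frame: pd.DataFrame, catalogue: pd.DataFrame
) -> dict[str, dict[str, SiteAlleleTable]]:
    """Inverse of :func:`tables_to_frames`."""
    out: dict[str, dict[str, SiteAlleleTable]] = {}
    for row in site_frame.itertuples(index=False):
        sub = catalogue[
            (catalogue["sample_id"] == row.sample_id)
            & (catalogue["site_id"] == row.site_id)
        ]
        alleles = [
            (
                IndelAllele(int(r.pos), r.type, int(r.length), r.seq),
                int(r.support),
                float(r.mrf),
            )
            for r in sub.itertuples(index=False)
        ]
        table = SiteAlleleTable(
            row.site_id,
            int(row.total_spanning_reads),
            alleles,
            int(row.wt_reads),
            int(row.unassigned),
        )
        table.validate()
        out.setdefault(row.sample_id, {})[row.site_id] = table
    return out


def compute_cohort_summary(
    tables_by_sample: dict[str, dict[str, SiteAlleleTable]],
    site_to_gene: dict[str, str] | None = None,
) -> dict:
    """Indel-spectrum summary over filtered tables across a cohort.

    Reports deletion/insertion event fractions and size extrema over
    allele-level events, plus the per-sample count of target genes carrying
    at least one filtered indel (sites of the same gene, e.g. the two
    Cdkn2a exons, collapse to one gene).
    """
    if not tables_by_sample:
        raise ValueError("need at least one sample")
    cat = indel_catalogue(tables_by_sample)
    n_events = len(cat)
    dels = cat[cat["type"] == "del"] if n_events else cat
    inss = cat[cat["type"] == "ins"] if n_events else cat
    genes_per_sample = {}
    for sample_id, tables in tables_by_sample.items():
        genes = set()
        for site_id, table in tables.items():
            if table.alleles:
                genes.add((site_to_gene or {}).get(site_id, site_id))
        genes_per_sample[sample_id] = len(genes)
    return {
        "n_events": n_events,
        "n_deletions": len(dels),
        "n_insertions": len(inss),
        "deletion_fraction": len(dels) / n_events if n_events else float("nan"),
        "insertion_fraction": len(inss) / n_events if n_events else float("nan"),
        "deletion_size_range": (
            (int(dels["length"].min()), int(dels["length"].max())) if len(dels) else None
        ),
        "insertion_size_range": (
            (int(inss["length"].min()), int(inss["length"].max())) if len(inss) else None
        ),
        "mutated_genes_per_sample": genes_per_sample,
        "mean_mrf": float(cat["mrf"].mean()) if n_events else float("nan"),
    }


# ---------------------------------------------------------------------------
# off-target screening


def offtarget_screen(
    tables_by_sample: dict[str, dict[str, SiteAlleleTable]],
    params: FilterParams,
) -> pd.DataFrame:
    """Per (sample, site) verdicts over a predicted off-target panel.

    A position is ``wild_type_only`` iff it has coverage and no allele
    survives the support filter; zero coverage yields ``no_data`` (absence
    of evidence, never a wild-type claim).
    """
    rows = []
    for sample_id, tables in tables_by_sample.items():
        for site_id, table in tables.items():
            filtered = filter_indels(table, params)
            if table.total_spanning_reads == 0:
                verdict = "no_data"
            elif filtered.alleles:
                verdict = "mutated"
            else:
                verdict = "wild_type_only"
            rows.append(
                {
                    "sample_id": sample_id,
                    "site_id": site_id,
                    "coverage": table.total_spanning_reads,
                    "verdict": verdict,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Surveyor (enzymatic mismatch cleavage) estimator


@dataclass(frozen=True)
class GelBands:
    """Integrated gel band intensities from a Surveyor cleavage assay."""

    uncut_intensity: float
    cut_intensities: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.uncut_intensity < 0 or any(c < 0 for c in self.cut_intensities):
            raise ValueError("band intensities must be non-negative")
        if self.uncut_intensity + sum(self.cut_intensities) <= 0:
            raise ValueError("total band intensity must be > 0")

    @property
    def cleaved_fraction(self) -> float:
        total = self.uncut_intensity + sum(self.cut_intensities)
        return sum(self.cut_intensities) / total


def surveyor_indel_fraction(bands: GelBands) -> float:
    """Editing efficiency from the cleaved-DNA fraction.

    Applies the duplex-reformation correction ``1 - sqrt(1 - f_cleaved)``:
    after denaturation/reannealing, only heteroduplexes (one wild-type and
    one mutant strand) are cleaved, so the cleaved fraction understates the
    mutant fraction.
    """
    f = bands.cleaved_fraction
    if f >= 1.0:
        warnings.warn("Surveyor assay saturated (all DNA cleaved)", stacklevel=2)
        return 1.0
    return 1.0 - math.sqrt(1.0 - f)
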