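"""Synthetic multiplexed-CRISPR cohort generator with full ground truth.

The generator emulates the statistical structure of deep amplicon
sequencing of clonal pancreatic tumours induced by multiplexed CRISPR/Cas9:

* NHEJ indel spectra strongly biased towards deletions (90% deletions,
  10% insertions), deletion sizes 1-363 bp and insertion sizes 1-32 bp with
  an inverse size-frequency relation (truncated geometric size laws), and
  indel anchors jittered 1-5 bp upstream of the PAM around the blunt cut;
* clonal tumours on a per-chromosome ploidy (2-7 copies), with every
  chromosome copy carrying an independent editing outcome, so multi-allelic
  sites arise naturally in polyploid clones;
* samples as mixtures of tumour clones plus stromal wild-type admixture;
  metastases inherit their parent clone's indel signature unchanged
  (CRISPR exposure was transient);
* MiSeq-like 2x300 bp paired amplicon reads with uniform substitution
  errors and a configurable fraction of discordant ("unpaired") pairs;
* junction amplicons for CRISPR-induced deletions and translocations whose
  breakpoints sit exactly at the cut sites.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .align import left_align_deletion, left_align_insertion
from .panel import TargetSite, revcomp

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))

JUNCTION_CLASSES = (
    "intra_deletion",
    "translocation_reciprocal",
    "translocation_nonreciprocal",
)


@dataclass(frozen=True)
class IndelAllele:
    """A normalized indel: left-aligned position, type, length and sequence."""

    pos: int
    type: str  # "del" | "ins"
    length: int
    seq: str

    @property
    def identity(self) -> tuple[int, str, int, str]:
        return (self.pos, self.type, self.length, self.seq)


def _truncated_geometric(mean: float, max_len: int) -> np.ndarray:
    """Geometric length law truncated to [1, max_len]; heavier mass on small sizes."""
    p = 1.0 / mean
    lengths = np.arange(1, max_len + 1)
    pmf = p * (1.0 - p) ** (lengths - 1)
    return pmf / pmf.sum()


@dataclass
class IndelModel:
    """NHEJ repair-outcome model at a Cas9 cut.

    ``p_deletion`` is the probability that a repair outcome is a deletion
    (the remainder are insertions). Size laws default to truncated
    geometrics (mean 6 bp for deletions capped at 363, mean 2 bp for
    insertions capped at 32) which reproduce the inverse size-frequency
    relation. ``pos_jitter`` spans the 1-5 bp window upstream of the PAM:
    anchors fall within +/- 2 bp of the blunt cut.
    """

    p_deletion: float = 0.9
    del_max: int = 363
    ins_max: int = 32
    del_mean: float = 6.0
    ins_mean: float = 2.0
    pos_jitter: int = 2
    del_len_probs: tuple[float, ...] | None = None  # explicit law over 1..del_max
    ins_len_probs: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_deletion <= 1.0:
            raise ValueError("p_deletion must be in [0, 1]")
        if self.del_max < 1 or self.ins_max < 1:
            raise ValueError("size caps must be >= 1")
        for probs, cap in ((self.del_len_probs, self.del_max), (self.ins_len_probs, self.ins_max)):
            if probs is not None and (
                len(probs) != cap or abs(sum(probs) - 1.0) > 1e-9
            ):
                raise ValueError("explicit length law must cover 1..max and sum to 1")
        self.del_len_dist = (
            np.asarray(self.del_len_probs)
            if self.del_len_probs is not None
            else _truncated_geometric(self.del_mean, self.del_max)
        )
        self.ins_len_dist = (
            np.asarray(self.ins_len_probs)
            if self.ins_len_probs is not None
            else _truncated_geometric(self.ins_mean, self.ins_max)
        )


def sample_indel(
    model: IndelModel, site: TargetSite, rng: np.random.Generator
) -> IndelAllele:
    """Draw one normalized indel allele at a site's cut position.

    Deletions whose span would leave less than 20 bp of amplicon on either
    side are resampled (and logged), mirroring the physical constraint that
    the amplicon must still be amplifiable and mappable.
    """
    ref = site.amplicon_seq
    for _attempt in range(100):
        is_del = rng.random() < model.p_deletion
        anchor = site.cut_pos + int(
            rng.integers(-model.pos_jitter, model.pos_jitter + 1)
        )
        if is_del:
            length = int(rng.choice(model.del_max, p=model.del_len_dist)) + 1
            start = anchor - length // 2
            if start < 20 or start + length > len(ref) - 20:
                logger.debug("deletion of %d bp out of bounds; resampled", length)
                continue
            pos, seq = left_align_deletion(ref, start, length)
            return IndelAllele(pos, "del", length, seq)
        length = int(rng.choice(model.ins_max, p=model.ins_len_dist)) + 1
        ins_seq = "".join(_BASES[rng.integers(0, 4, size=length)])
        pos, seq = left_align_insertion(ref, anchor, ins_seq)
        return IndelAllele(pos, "ins", length, seq)
    raise RuntimeError(f"could not place an indel at {site.site_id}")


def apply_indel(amplicon: str, allele: IndelAllele | None) -> str:
    """Mutated amplicon sequence for one allele (None = wild-type)."""
    if allele is None:
        return amplicon
    if allele.type == "del":
        return amplicon[: allele.pos] + amplicon[allele.pos + allele.length :]
    return amplicon[: allele.pos] + allele.seq + amplicon[allele.pos :]


# ---------------------------------------------------------------------------
# clones and samples


@dataclass
class CloneTruth:
    """Ground-truth genotype of one tumour clone.

    ``alleles`` maps (site_id, chromosome copy index) to an
    :class:`IndelAllele` or ``None`` (wild-type copy); each site has exactly
    ``ploidy[chrom]`` slots. ``rearrangements`` lists
    (site_a, site_b, class) structural events carried by the clone.
    """

    clone_id: str
    ploidy: dict[str, int]
    alleles: dict[tuple[str, int], IndelAllele | None]
    rearrangements: list[tuple[str, str, str]] = field(default_factory=list)

    def copies(self, site: TargetSite) -> list[IndelAllele | None]:
        k = self.ploidy[site.chrom]
        return [self.alleles.get((site.site_id, c)) for c in range(k)]

    def signature(self) -> set[tuple[str, tuple]]:
        """Set of (site_id, indel identity) markers — the clonal barcode."""
        return {
            (sid, allele.identity)
            for (sid, _c), allele in self.alleles.items()
            if allele is not None
        }

    def validate(self, panel: list[TargetSite]) -> None:
        for site in panel:
            k = self.ploidy.get(site.chrom)
            if k is None or k < 1:
                raise ValueError(f"{self.clone_id}: no ploidy for {site.chrom}")
            extra = [
                c for (sid, c) in self.alleles if sid == site.site_id and c >= k
            ]
            if extra:
                raise ValueError(
                    f"{self.clone_id}: allele slots beyond ploidy at {site.site_id}"
                )


def simulate_clone(
    clone_id: str,
    panel: list[TargetSite],
    ploidy: dict[str, int],
    model: IndelModel,
    rng: np.random.Generator,
    p_delivery: float = 0.8,
    p_copy_edit: float = 0.9,
    blocked_genes: tuple[str, ...] = (),
) -> CloneTruth:
    """Simulate editing outcomes for one clone.

    Each sgRNA reaches the clone's founder cell with probability
    ``p_delivery``; a delivered guide then edits each chromosome copy
    independently with probability ``p_copy_edit``. Genes in
    ``blocked_genes`` are never edited (emulating negative selection of
    clones carrying those mutations among viable tumours).
    """
    alleles: dict[tuple[str, int], IndelAllele | None] = {}
    for site in panel:
        k = ploidy[site.chrom]
        delivered = rng.random() < p_delivery and site.gene not in blocked_genes
        for c in range(k):
            if delivered and rng.random() < p_copy_edit:
                alleles[(site.site_id, c)] = sample_indel(model, site, rng)
            else:
                alleles[(site.site_id, c)] = None
    return CloneTruth(clone_id, dict(ploidy), alleles)


def metastasis_clone(parent: CloneTruth, met_id: str) -> CloneTruth:
    """A metastatic descendant: identical signature to its parent clone."""
    return CloneTruth(
        met_id, dict(parent.ploidy), dict(parent.alleles), list(parent.rearrangements)
    )


SAMPLE_KINDS = ("tumour_tissue", "cell_line", "single_cell_clone", "metastasis", "normal")


@dataclass
class SampleTruth:
    """One sequenced sample: a clone mixture plus stromal wild-type DNA."""

    sample_id: str
    kind: str
    clone_mixture: dict[str, float]
    stromal_wt_fraction: float = 0.0
    parent_primary: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in SAMPLE_KINDS:
            raise ValueError(f"unknown sample kind {self.kind!r}")
        total = sum(self.clone_mixture.values()) + self.stromal_wt_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"{self.sample_id}: mixture + stromal fraction must sum to 1, got {total}"
            )
        if self.kind == "metastasis" and self.parent_primary is None:
            raise ValueError(f"{self.sample_id}: metastasis needs parent_primary")


def expected_site_fractions(
    sample: SampleTruth,
    clones: dict[str, CloneTruth],
    site: TargetSite,
) -> dict[IndelAllele | None, float]:
    """Expected read fractions per allele (None = wild-type) at one site.

    Clone fractions are split uniformly across chromosome copies, so an
    allele on c of k copies of a clone at mixture fraction f contributes
    f * c / k. Fractions sum to 1 by construction.
    """
    fracs: dict[IndelAllele | None, float] = {None: sample.stromal_wt_fraction}
    for clone_id, f in sample.clone_mixture.items():
        copies = clones[clone_id].copies(site)
        for allele in copies:
            fracs[allele] = fracs.get(allele, 0.0) + f / len(copies)
    return fracs


# ---------------------------------------------------------------------------
# read simulation


@dataclass
class SimConfig:
    """Sequencing-run configuration (MiSeq-like 2x300 bp paired-end)."""

    seed: int = 0
    coverage_per_site: int = 1000
    read_length: int = 300
    substitution_error_rate: float = 0.001
    unpaired_fraction: float = 0.03
    indel_model: IndelModel = field(default_factory=IndelModel)
    rearrangements: list[tuple[str, str, str]] = field(default_factory=list)
    junction_coverage_scale: float = 0.5

    def __post_init__(self) -> None:
        if self.coverage_per_site <= 0:
            raise ValueError("coverage_per_site must be > 0")
        if not 0.0 <= self.unpaired_fraction <= 1.0:
            raise ValueError("unpaired_fraction must be in [0, 1]")


def _add_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        current = arr[i].decode()
        choices = [b for b in "ACGT" if b != current]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode()


def _template_reads(
    template: str, read_length: int, rate: float, rng: np.random.Generator
) -> tuple[str, str]:
    r1 = template[:read_length]
    r2 = revcomp(template[-read_length:])
    return _add_errors(r1, rate, rng), _add_errors(r2, rate, rng)


def simulate_junction_amplicon(
    site_a: TargetSite,
    site_b: TargetSite,
    junction_class: str,
    rng: np.random.Generator | None = None,
    junction_indel_prob: float = 0.0,
) -> list[tuple[str, str]]:
    """Junction reference sequence(s) for a CRISPR-induced fusion.

    The A->B derivative joins A's amplicon prefix up to its cut with B's
    amplicon suffix from its cut, so the breakpoint sits exactly at both
    sgRNA cut sites. Reciprocal translocations also emit the B->A
    derivative. With ``junction_indel_prob`` a small NHEJ indel is placed at
    the seam.
    """
    if site_a.site_id == site_b.site_id:
        raise ValueError("junction requires two distinct sites")
    if junction_class not in JUNCTION_CLASSES:
        raise ValueError(f"unknown junction class {junction_class!r}")
    rng = rng or np.random.default_rng(0)

    def seam(sa: TargetSite, sb: TargetSite) -> tuple[str, str]:
        seq = sa.amplicon_seq[: sa.cut_pos] + sb.amplicon_seq[sb.cut_pos :]
        if junction_indel_prob and rng.random() < junction_indel_prob:
            d = int(rng.integers(1, 4))
            seq = seq[: sa.cut_pos - d] + seq[sa.cut_pos :]
        return (f"{sa.site_id}--{sb.site_id}", seq)

    out = [seam(site_a, site_b)]
    if junction_class == "translocation_reciprocal":
        out.append(seam(site_b, site_a))
    return out


def simulate_sample_reads(
    sample: SampleTruth,
    clones: dict[str, CloneTruth],
    panel: list[TargetSite],
    config: SimConfig,
    rng: np.random.Generator,
) -> list[tuple[str, str, str]]:
    """Paired reads for one sample: list of (pair_id, read1, read2).

    Per site, ``coverage_per_site`` fragments are drawn from allele-bearing
    amplicons proportional to the clone mixture and stromal fraction. An
    ``unpaired_fraction`` of pairs get their second mate replaced by a read
    from another amplicon, emulating discordant pairs that the pairing
    filter must drop. Junction amplicons carried by sampled clones are
    sequenced at ``junction_coverage_scale`` times the clone-weighted
    coverage.
    """
    site_by_id = {s.site_id: s for s in panel}
    reads: list[tuple[str, str, str]] = []
    err = config.substitution_error_rate
    for site in panel:
        fracs = expected_site_fractions(sample, clones, site)
        alleles = list(fracs)
        probs = np.array([fracs[a] for a in alleles])
        probs = probs / probs.sum()
        templates = [apply_indel(site.amplicon_seq, a) for a in alleles]
        picks = rng.choice(len(alleles), size=config.coverage_per_site, p=probs)
        for i, pick in enumerate(picks):
            r1, r2 = _template_reads(templates[pick], config.read_length, err, rng)
            reads.append((f"{sample.sample_id}:{site.site_id}:{i}", r1, r2))

    # structural-variant junction amplicons carried by the sampled clones
    seen: set[tuple[str, str, str]] = set()
    for clone_id, frac in sample.clone_mixture.items():
        events = list(clones[clone_id].rearrangements) + list(config.rearrangements)
        for site_a_id, site_b_id, cls in events:
            if (site_a_id, site_b_id, cls) in seen:
                continue
            seen.add((site_a_id, site_b_id, cls))
            if site_a_id not in site_by_id or site_b_id not in site_by_id:
                raise ValueError(f"rearrangement references unknown site {site_a_id}/{site_b_id}")
            juncs = simulate_junction_amplicon(
                site_by_id[site_a_id], site_by_id[site_b_id], cls, rng
            )
            n = int(config.coverage_per_site * frac * config.junction_coverage_scale)
            for junc_id, junc_seq in juncs:
                for i in range(n):
                    r1, r2 = _template_reads(junc_seq, config.read_length, err, rng)
                    reads.append((f"{sample.sample_id}:{junc_id}:{i}", r1, r2))

    # discordant pairs: replace mate 2 with a read from a different amplicon
    if config.unpaired_fraction > 0 and len(panel) > 1:
        n_swap = int(round(config.unpaired_fraction * len(reads)))
        idx = rng.choice(len(reads), size=n_swap, replace=False)
        for i in idx:
            pair_id, r1, _r2 = reads[i]
            own = pair_id.split(":")[1]
            others = [p for p in panel if p.site_id != own]
            other = others[int(rng.integers(0, len(others)))]
            # mate 2 drawn in the same (reverse) orientation from another amplicon
            _x1, x2 = _template_reads(other.amplicon_seq, config.read_length, err, rng)
            reads[i] = (pair_id, r1, x2)
    rng.shuffle(reads)
    return reads


# ---------------------------------------------------------------------------
# cohort-level driver and truth tables


def truth_tables(
    clones: dict[str, CloneTruth],
    samples: list[SampleTruth],
    panel: list[TargetSite],
) -> dict[str, pd.DataFrame]:
    """Ground-truth tables: clone alleles, sample mixtures, expected MRFs."""
    allele_rows = []
    for clone in clones.values():
        for (sid, c), allele in sorted(clone.alleles.items()):
            allele_rows.append(
                {
                    "clone_id": clone.clone_id,
                    "site_id": sid,
                    "copy": c,
                    "type": "wt" if allele is None else allele.type,
                    "pos": None if allele is None else allele.pos,
                    "length": None if allele is None else allele.length,
                    "seq": None if allele is None else allele.seq,
                }
            )
    mix_rows = []
    for s in samples:
        for clone_id, f in s.clone_mixture.items():
            mix_rows.append(
                {
                    "sample_id": s.sample_id,
                    "kind": s.kind,
                    "clone_id": clone_id,
                    "fraction": f,
                    "stromal_wt_fraction": s.stromal_wt_fraction,
                    "parent_primary": s.parent_primary,
                }
            )
    mrf_rows = []
    for s in samples:
        for site in panel:
            fracs = expected_site_fractions(s, clones, site)
            wt = fracs.get(None, 0.0)
            mrf_rows.append(
                {
                    "sample_id": s.sample_id,
                    "site_id": site.site_id,
                    "expected_wt_fraction": wt,
                    "expected_cumulative_mrf": 1.0 - wt,
                    "n_alleles": sum(1 for a in fracs if a is not None and fracs[a] > 0),
                }
            )
    return {
        "clone_alleles": pd.DataFrame(allele_rows),
        "sample_mixtures": pd.DataFrame(mix_rows),
        "expected_mrfs": pd.DataFrame(mrf_rows),
    }


def write_fastq_pair(
    reads: list[tuple[str, str, str]], prefix: Path, compress: bool = False
) -> tuple[Path, Path]:
    suffix = ".fastq.gz" if compress else ".fastq"
    p1 = prefix.with_name(prefix.name + "_R1" + suffix)
    p2 = prefix.with_name(prefix.name + "_R2" + suffix)
    opener = gzip.open if compress else open
    with opener(p1, "wt") as f1, opener(p2, "wt") as f2:
        for pair_id, r1, r2 in reads:
            f1.write(f"@{pair_id}/1\n{r1}\n+\n{'I' * len(r1)}\n")
            f2.write(f"@{pair_id}/2\n{r2}\n+\n{'I' * len(r2)}\n")
    return p1, p2


def read_fastq_pair(p1: Path, p2: Path) -> list[tuple[str, str, str]]:
    from Bio import SeqIO

    def _records(path: Path):
        op = gzip.open if str(path).endswith(".gz") else open
        with op(path, "rt") as fh:
            for rec in SeqIO.parse(fh, "fastq"):
                yield rec.id.rsplit("/", 1)[0], str(rec.seq)

    out = []
    for (id1, s1), (id2, s2) in zip(_records(p1), _records(p2), strict=True):
        if id1 != id2:
            raise ValueError(f"FASTQ pair mismatch: {id1} vs {id2}")
        out.append((id1, s1, s2))
    return out


def simulate_cohort(
    config: SimConfig,
    panel: list[TargetSite],
    clones: dict[str, CloneTruth],
    samples: list[SampleTruth],
    out_dir: str | Path | None = None,
) -> dict[str, list[tuple[str, str, str]]]:
    """Simulate reads for every sample; optionally write FASTQ + truth TSVs.

    With a fixed ``config.seed`` the outputs are byte-identical across runs.
    """
    for clone in clones.values():
        clone.validate(panel)
    rng = np.random.default_rng(config.seed)
    reads_by_sample: dict[str, list[tuple[str, str, str]]] = {}
    for sample in samples:
        for clone_id in sample.clone_mixture:
            if clone_id not in clones:
                raise ValueError(f"{sample.sample_id}: unknown clone {clone_id}")
        reads_by_sample[sample.sample_id] = simulate_sample_reads(
            sample, clones, panel, config, rng
        )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for sample_id, reads in reads_by_sample.items():
            write_fastq_pair(reads, out / sample_id)
        for name, frame in truth_tables(clones, samples, panel).items():
            frame.to_csv(out / f"truth_{name}.tsv", sep="\t", index=False)
    return reads_by_sample
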