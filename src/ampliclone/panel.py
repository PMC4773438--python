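"""Target-site panels for multiplexed CRISPR amplicon sequencing.

A *target site* is one sgRNA locus: the PCR amplicon that is deep-sequenced,
the 20-nt protospacer with its 3-nt PAM, and the blunt Cas9 cut position,
which lies 3 nt 5' of the PAM-proximal end of the protospacer. All
coordinates are 0-based, half-open, in amplicon space; the cut falls between
``cut_pos - 1`` and ``cut_pos``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: offset of the blunt cut from the PAM-proximal protospacer end
CUT_OFFSET_FROM_PAM = 3


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TargetSite:
    """One sgRNA target locus on its sequencing amplicon.

    Parameters
    ----------
    site_id : unique label, e.g. ``"Trp53"`` or ``"Cdkn2a-ex1b"``.
    chrom : chromosome label the amplicon maps to (e.g. ``"chr11"``).
    amplicon_seq : the amplified reference sequence (300-600 nt).
    protospacer : 20-nt guide-matching sequence, given 5'->3' on the guide
        strand.
    pam : 3-nt PAM immediately 3' of the protospacer on the guide strand.
    strand : ``"+"`` if the protospacer+PAM read directly from
        ``amplicon_seq``, ``"-"`` if from its reverse complement.
    cut_pos : amplicon offset of the blunt double-strand break (0-based; the
        cut is between ``cut_pos - 1`` and ``cut_pos``).
    gene : gene symbol for gene-level summaries (defaults to ``site_id``).
    genomic_cut : optional genomic coordinate of the cut, used only for
        predicted deletion spans between same-chromosome sites.
    """

    site_id: str
    chrom: str
    amplicon_seq: str
    protospacer: str
    pam: str
    strand: str
    cut_pos: int
    gene: str | None = None
    genomic_cut: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if len(self.protospacer) != 20:
            raise ValueError("protospacer must be 20 nt")
        if len(self.pam) != 3:
            raise ValueError("PAM must be 3 nt")
        if not (0 < self.cut_pos < len(self.amplicon_seq)):
            raise ValueError("cut_pos outside amplicon")
        if self.gene is None:
            object.__setattr__(self, "gene", self.site_id)
        self._check_guide_placement()

    def _check_guide_placement(self) -> None:
        guide = self.protospacer + self.pam
        if self.strand == "+":
            p = self.amplicon_seq.find(guide)
            if p < 0:
                raise ValueError(f"{self.site_id}: protospacer+PAM not on + strand")
            expected_cut = p + 20 - CUT_OFFSET_FROM_PAM
        else:
            p = self.amplicon_seq.find(revcomp(guide))
            if p < 0:
                raise ValueError(f"{self.site_id}: protospacer+PAM not on - strand")
            # forward coords: revcomp(PAM) occupies [p, p+3), protospacer
            # PAM-proximal end is at p+3; cut is 3 nt into the protospacer
            expected_cut = p + 3 + CUT_OFFSET_FROM_PAM
        if expected_cut != self.cut_pos:
            raise ValueError(
                f"{self.site_id}: cut_pos {self.cut_pos} violates the "
                f"3-bp-5'-of-PAM convention (expected {expected_cut})"
            )


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _embed_guide(
    amplicon: list[str], cut_pos: int, strand: str, rng: np.random.Generator
) -> tuple[str, str]:
    """Force an NGG PAM consistent with ``cut_pos`` and return (protospacer, pam)."""
    if strand == "+":
        p = cut_pos - 17  # protospacer start
        amplicon[p + 21] = "G"
        amplicon[p + 22] = "G"
        proto = "".join(amplicon[p : p + 20])
        pam = "".join(amplicon[p + 20 : p + 23])
    else:
        q = cut_pos - 6  # revcomp(PAM) start on the forward strand
        amplicon[q] = "C"
        amplicon[q + 1] = "C"
        proto = revcomp("".join(amplicon[q + 3 : q + 23]))
        pam = revcomp("".join(amplicon[q : q + 3]))
    return proto, pam


def simulate_panel(
    n_sites: int,
    chrom_layout: dict[str, str] | None = None,
    seed: int = 0,
    amplicon_length: int = 400,
    site_ids: list[str] | None = None,
    genes: dict[str, str] | None = None,
    genomic_cuts: dict[str, int] | None = None,
) -> list[TargetSite]:
    """Simulate a panel of amplicon target sites.

    ``chrom_layout`` maps each site_id to a chromosome label; when omitted
    each site gets its own chromosome. Amplicons are 400 nt with the cut
    placed in the central 30-70% span so that 300-nt paired reads always
    cover the cut-site counting window from both sides.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    if site_ids is None:
        site_ids = [f"site{i + 1:02d}" for i in range(n_sites)]
    if len(site_ids) != n_sites or len(set(site_ids)) != n_sites:
        raise ValueError("site_ids must be unique and match n_sites")
    if chrom_layout is None:
        chrom_layout = {sid: f"chr{i + 1}" for i, sid in enumerate(site_ids)}
    missing = [s for s in site_ids if s not in chrom_layout]
    if missing:
        raise ValueError(f"chrom_layout missing sites: {missing}")

    sites = []
    for sid in site_ids:
        lo = int(amplicon_length * 0.30)
        hi = int(amplicon_length * 0.70)
        cut_pos = int(rng.integers(lo, hi))
        strand = "+" if rng.random() < 0.5 else "-"
        amp = list(_random_seq(rng, amplicon_length))
        proto, pam = _embed_guide(amp, cut_pos, strand, rng)
        sites.append(
            TargetSite(
                site_id=sid,
                chrom=chrom_layout[sid],
                amplicon_seq="".join(amp),
                protospacer=proto,
                pam=pam,
                strand=strand,
                cut_pos=cut_pos,
                gene=(genes or {}).get(sid),
                genomic_cut=(genomic_cuts or {}).get(sid),
            )
        )
    return sites


# The 15-site study panel: 2 neutral Rosa26 sites plus 13 tumour-suppressor
# sgRNAs, with chromosome assignments taken from the mouse genome. Four
# chromosomes carry more than one site (chr4 x4, chr6 x2, chr11 x2, chr18 x2),
# giving nine possible intra-chromosomal fusions. Amplicon sequences are
# synthetic; the genomic cut coordinates of the Cdkn2a exon-1beta/exon-2 pair
# are synthetic approximations of mm10 geometry (~18 kb apart).
STUDY_PANEL_LAYOUT: dict[str, str] = {
    "Cdkn2a-ex1b": "chr4",
    "Cdkn2a-ex2": "chr4",
    "Cdkn2b": "chr4",
    "Arid1a": "chr4",
    "Rosa26.1": "chr6",
    "Rosa26.2": "chr6",
    "Trp53": "chr11",
    "Brca1": "chr11",
    "Apc": "chr18",
    "Smad4": "chr18",
    "Brca2": "chr5",
    "Pten": "chr19",
    "Arid1b": "chr17",
    "Tgfbr2": "chr9",
    "Acvr1b": "chr15",
}

STUDY_PANEL_GENES: dict[str, str] = {
    "Cdkn2a-ex1b": "Cdkn2a",
    "Cdkn2a-ex2": "Cdkn2a",
    "Rosa26.1": "Rosa26",
    "Rosa26.2": "Rosa26",
}

# synthetic genomic cut coordinates (bp); the Cdkn2a pair is ~18 kb apart
STUDY_PANEL_GENOMIC_CUTS: dict[str, int] = {
    "Cdkn2a-ex1b": 89_294_000,
    "Cdkn2a-ex2": 89_276_000,
    "Cdkn2b": 89_311_000,
    "Arid1a": 133_680_000,
    "Rosa26.1": 113_067_000,
    "Rosa26.2": 113_069_500,
    "Trp53": 69_580_000,
    "Brca1": 101_500_000,
    "Apc": 34_270_000,
    "Smad4": 73_640_000,
}


def study_panel(seed: int = 7) -> list[TargetSite]:
    """The 15-site reference panel used throughout the analyses."""
    ids = list(STUDY_PANEL_LAYOUT)
    return simulate_panel(
        len(ids),
        chrom_layout=STUDY_PANEL_LAYOUT,
        seed=seed,
        site_ids=ids,
        genes=STUDY_PANEL_GENES,
        genomic_cuts=STUDY_PANEL_GENOMIC_CUTS,
    )


def offtarget_panel(n_sites: int = 108, seed: int = 11) -> list[TargetSite]:
    """A panel of predicted off-target loci (same schema as target sites)."""
    ids = [f"OT{i + 1:03d}" for i in range(n_sites)]
    layout = {sid: f"chr{(i % 19) + 1}" for i, sid in enumerate(ids)}
    return simulate_panel(n_sites, chrom_layout=layout, seed=seed, site_ids=ids)


def write_panel_fasta(sites: list[TargetSite], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.amplicon_seq), id=s.site_id, description=f"chrom={s.chrom}")
        for s in sites
    ]
    SeqIO.write(records, str(path), "fasta")


def panel_to_frame(sites: list[TargetSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "site_id": s.site_id,
                "chrom": s.chrom,
                "strand": s.strand,
                "protospacer": s.protospacer,
                "pam": s.pam,
                "cut_pos": s.cut_pos,
                "gene": s.gene,
                "genomic_cut": s.genomic_cut,
                "amplicon_length": len(s.amplicon_seq),
            }
            for s in sites
        ]
    )


def write_panel_tsv(sites: list[TargetSite], path: str | Path) -> None:
    panel_to_frame(sites).to_csv(path, sep="\t", index=False)


def load_panel(tsv_path: str | Path, fasta_path: str | Path) -> list[TargetSite]:
    """Reconstruct a panel from its TSV + amplicon FASTA export."""
    frame = pd.read_csv(tsv_path, sep="\t")
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    sites = []
    for row in frame.itertuples(index=False):
        sites.append(
            TargetSite(
                site_id=row.site_id,
                chrom=row.chrom,
                amplicon_seq=seqs[row.site_id],
                protospacer=row.protospacer,
                pam=row.pam,
                strand=row.strand,
                cut_pos=int(row.cut_pos),
                gene=None if pd.isna(row.gene) else row.gene,
                genomic_cut=None if pd.isna(row.genomic_cut) else int(row.genomic_cut),
            )
        )
    return sites
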