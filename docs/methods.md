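# Methods

## Scope and model

`ampliclone` analyses deep paired-end amplicon sequencing of multiplexed
CRISPR/Cas9 editing outcomes in clonal tumours, and ships a synthetic
cohort generator that emulates the data-generating process so every
estimator can be validated against ground truth. The package treats a
tumour as a clone whose genotype was fixed during one transient burst of
Cas9 activity: per chromosome copy, each delivered guide either left the
locus intact or wrote one NHEJ indel, and all later samples (biopsies,
cell cultures, metastases) are mixtures of such clones plus stromal
wild-type DNA.

## Synthetic data generator

The generator's defaults are the study conditions the analyses assume:

| parameter | default | meaning |
| --- | --- | --- |
| `p_deletion` | 0.9 | NHEJ outcomes are 90% deletions / 10% insertions |
| deletion sizes | geometric, mean 6 bp, truncated at 363 | inverse size–frequency relation; sizes 1–363 bp |
| insertion sizes | geometric, mean 2 bp, truncated at 32 | sizes 1–32 bp |
| `pos_jitter` | ±2 bp around the cut | indel anchors 1–5 bp upstream of the PAM |
| `p_delivery` | 0.8 per guide | probability a guide acts in the founder cell |
| `p_copy_edit` | 0.9 per copy | per-chromosome-copy editing given delivery |
| read length | 2×300 bp paired | MiSeq-like amplicon reads |
| substitution error | 0.1% per base | uniform; no quality profile |
| `unpaired_fraction` | 0.03 | discordant pairs the pairing filter must drop |
| amplicons | 400 nt, cut in the central 30–70% | both mates always span the cut window |

Size laws are not dictated beyond their ranges and the inverse
size–frequency relation, so truncated geometrics were chosen once;
explicit probability vectors can be substituted. The per-guide delivery
probability 0.8 reproduces 7–14 mutated genes per 15-guide tumour
(Binomial thinning); `Brca2` is excluded from viable tumour clones to
emulate negative selection. The per-copy editing probability 0.9 reflects
guides pre-validated for high cleavage efficiency; the cohort's
complete-inactivation fraction is an emergent consequence of it and the
ploidy mix, not a fitted quantity. Metastasis clones copy their parent
genotype exactly (Cas9 exposure was transient); a drift option exists for
robustness experiments.

What the generator deliberately does **not** model: PCR amplification
bias and chimeras, quality-score-dependent errors, indel sequencing
errors (errors are substitution-only), microhomology-directed repair
spectra, and subclonal evolution after editing. Passing tests therefore
demonstrate correctness of the estimators under clean clonal mixtures,
not robustness to every artefact of real libraries — in particular the
substitution-only error model is what makes read clustering (below)
exact.

## Alignment

Reads are aligned semi-globally (query global, reference ends free)
with affine gaps — match +2, mismatch −4, gap of length L costing
−(6 + L) — plus a **long-deletion jump**: any reference gap of ≥ 30 bp
may instead be taken for a flat −24. The flat state makes a single
100–400 bp deletion the optimal representation where a plain affine
scheme would fragment or clip the read. Traceback ties prefer, in order:
diagonal, long deletion, affine deletion, insertion — i.e. the fewest
indel operations, with indels pushed leftmost. The recurrence is a
four-state Gotoh DP; the jump state uses a per-row running maximum with a
30-column lag, keeping the fill O(mn). The implementation is
numba-compiled; tests check exact score agreement with an independent
oracle that enumerates every gap length explicitly.

Indel observations are reported **left-aligned** against the amplicon
(normalization is idempotent and representation-invariant), and only
indels overlapping the cut ± 20 bp window are counted; reads whose
alignment does not span that window are excluded from the site
denominator. Alignments ending in a long terminal insertion are treated
as clipped (the read only partially belongs to the reference, e.g. one
arm of an unanticipated fusion) and dropped.

### Read assignment and clustering

Mates are assigned to amplicons by edlib infix edit distance over both
orientations; a pair is kept only if both mates hit the same reference in
opposite orientations. Whole-read edit distance misses reads spanning
deletions longer than the distance cap, so unassigned reads fall back to
probing in thirds: segments agreeing on one amplicon assign the read,
segments from different amplicons (junction chimeras) leave it
unassigned. A hit within 3 edits ends the scan early — references differ
from one another by far more than a read's expected error count.

For speed, distinct read sequences seen ≥ 3 times (error-free haplotype
reads — amplicon fragments are identical, so these dominate) are aligned
by the full DP and become cluster representatives; rarer sequences that
differ from a representative only by substitutions inherit its operation
structure, with the score recomputed honestly for the actual bases. Under
the substitution-only error model this clustering is exact; on real data
it would be an approximation and can be disabled by setting
`rep_min_count=1`.

## Calling and filtering

A pair contributes once per site: the union of its mates' windowed,
normalized indels is its haplotype. Identical indels merge into alleles
with pair-level support; a pair showing two or more distinct windowed
indels (at these error rates an alignment artefact) is tallied as
*unassigned*, never invented as a composite allele, so count conservation
`wt + Σ support + unassigned = spanning` holds at every stage. The
support filter keeps alleles with support **strictly greater** than
`min_mutant_reads` (documented default 100 for full MiSeq depth; scaled
as `max(10, 1% of coverage)` for desk-scale simulations) and MRF above an
error floor of 0.5% — the floor operationalizes "above sequencing error
rates", which is not otherwise quantified. Removed support goes to the
unassigned tally, not to wild-type.

## Zygosity and copy assignment

Complete inactivation is called in cell cultures when the wild-type
fraction is ≤ `wt_epsilon` (default 0.01 — a literal zero is unattainable
at a 0.1% error rate) and at least one allele survives filtering; tissue
samples only ever receive `mutated_zygosity_indeterminate`. Copy
assignment searches all compositions of the karyotype copy number k
(k ≤ 12; the search is exhaustive and exact) for the least-squares fit to
observed frequencies; ties are flagged ambiguous and broken toward
retaining wild-type copies. More alleles than copies above a 1% noise
floor is flagged infeasible (subclonality or a wrong karyotype). The
number of distinct surviving alleles, plus one if wild-type persists, is
a lower bound on the copy number at editing time.

## Lineage tracking

Signatures are sets of exact (site, position, type, length, sequence)
markers from filtered tables; a relaxed position+length mode exists for
noisier callers. Samples are clustered by single linkage on Jaccard
distance with a 0.3 threshold; a sample is *mixed* when ≥ 2 clusters each
explain ≥ `min_shared` (default 2) of its markers **not explained by a
larger-contributing cluster** — the novelty condition prevents a pure
sample's subset-overlap with a mixture's hybrid cluster from counting as
evidence. Mixed calls are made against clusters of pure samples only
(two-pass). Metastases are assigned to the primary sharing the most
markers, requiring ≥ 2 shared and a margin of ≥ 1 over the runner-up;
anything less is reported ambiguous. Dendrograms export to Newick via
scikit-bio.

## Rearrangement screen

Intra-chromosomal candidates are unordered same-chromosome pairs modelled
as head-to-tail deletion joins (inversion-type joins are excluded: pair
counting reproduces the expected nine candidates on the 15-site panel);
cross-chromosome pairs are enumerated in both derivative orientations.
The predicted junction is A's amplicon prefix up to its cut joined to B's
suffix from its cut; junction references participate in read assignment
so fusion reads are never forced onto target amplicons. A read confirms a
junction when it spans the seam by ≥ 30 aligned bases on each side and
any seam-local indel keeps both breakpoint offsets within 10 bp (NHEJ
junction resection); same-chromosome calls are deletions,
cross-chromosome calls are reciprocal if both derivatives are detected,
else non-reciprocal.

## Surveyor estimator

Editing efficiency from mismatch-cleavage gels is
`1 − sqrt(1 − f_cleaved)` with `f_cleaved` the cleaved fraction of
integrated band intensity; the square root is the standard
duplex-reformation correction (only heteroduplexes are cut, and mutant
strands re-pair with wild-type strands at random). The formula fixes
0 → 0 and 1 → 1 and is monotone; a fully cleaved assay returns 1 with a
saturation warning.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale versions of the study design
chosen for single-CPU execution: the cohort summary at 600–800× per
site, allele-copy recovery at 5000× (k = 2..7), lineage recovery over 50
seeded replicates at 1000× with 4 sites and 3 biopsies per cohort, the
rearrangement round trip at 200–300×, and the off-target screen at
108 sites × 6 samples × 200–250×. Binomial confidence intervals are
two-sided 99%; copy-assignment residual ties use a 1e-12 quantization;
seeds derived from a master seed stay below 2³¹.

## Known limitations

- The support filter is applied per sample per site; pooling across
  samples is not implemented.
- Micro-homology annotation, SNV calling and base-editing outcomes are
  out of scope.
- Junction detection assumes the fusion preserves both amplicon flanks;
  deletions whose boundaries extend beyond the amplicons (detected by
  aCGH in real studies) are invisible to the fusion-PCR-style screen.
- Copy assignment assumes one clone; mixed samples violate the
  composition model and surface as infeasible or high-residual fits.
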