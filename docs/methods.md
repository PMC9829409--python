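# Methods

This note documents the models and procedures implemented in
`dualguide`, the parameters that matter, the design choices made where
the design was genuinely open, and what the synthetic-data tests do
and do not demonstrate.

## Tiered guide selection

Guide selection aggregates empirical activity across prior CRISPRi
screens, falling back to predicted activity only when no empirical
signal exists.

**Inputs.** A guide-candidate table (gene, 19–20-nt protospacer,
predicted activity score — consumed as a column, never recomputed), a
per-screen guide table (phenotype, guide-level FDR), a per-screen gene
table (p-value, gene-level FDR, and gene-level γ for the K562
reference screen), and an olfactory-receptor gene list supplied as
input. Guides containing a BsmBI recognition site (`CGTCTC` or
`GAGACG`; mutual reverse complements, so scanning the protospacer
string for both covers both strands) are removed first because the
tandem cassette is cloned by BsmBI Golden Gate.

**Tiers.** Tier 1: K562 p < 0.001 and γ < −0.2 (both thresholds
configurable in `DesignConfig`). Tier 2: gene hit (FDR ≤ 0.05) in ≥ 5
screens; or hit in 1–4 screens with discriminant score above the
olfactory null threshold. Tier 3: everything else. Precedence is
strictly 1 > 2 > 3; every gene receives exactly one tier. A gene
absent from the K562 table simply fails the tier-1 test (logged at
debug level).

**Discriminant score.** Per hit screen,
`d = (−log₁₀ p) × mean(z of the top-3 guides)` where z-scores are
computed within each screen across *all* guides (population SD), "top"
means largest |z|, and the sign of the mean is kept; the gene score is
`Σ |d|` over hit screens. Choices made where the source procedure is
underdetermined:

* *Top-3 with fewer than 3 measured guides*: use all available guides
  rather than dropping the gene — discarding sparsely measured genes
  would silently shrink tier 2.
* *Multiple gene records in one screen* (e.g. per-transcript or
  per-direction rows): take the record maximizing |d|; with a single
  record this is the identity.
* *Olfactory threshold*: the **maximum** olfactory score at exactly k
  hit screens (k = 1..4), falling back to the maximum over ≤ k when no
  olfactory gene has exactly k hits, and +∞ when the null set is empty
  — the most conservative reading, guaranteeing no olfactory gene
  would pass its own threshold. A quantile would admit some.

**Ranking.** Tier 1 ranks by mean relative phenotype (each screen's
phenotypes divided by the gene's best — largest |value| — guide, so
the best guide maps to 1.0 and screens with different effect scales
are comparable); tier 2 ranks guides that were themselves hits (guide
FDR < 0.01 in ≥ 1 hit screen) by mean relative phenotype, with
non-hit guides after them by predicted score; tier 3 by predicted
score. All ties break by ascending protospacer lexicographic order so
designs are byte-stable across runs.

**Elements.** Sublibrary `1_2` pairs ranks 1+2, `3_4` ranks 3+4,
`5_6` ranks 5+6; a gene joins as many sublibraries as its surviving
guide count allows. Non-targeting control pairs are appended at
`n = ceil(T·f/(1−f))` for T targeting elements and control fraction f
(default 0.05), taken **in input order** from a user-supplied pool —
no internal randomness, so designs reproduce without a seed. The
synthesis oligo is the exact concatenation
`adaptor5 + CCACCTTGTTG + A + GTTTCAGAGCGAGACGTGCCTGCAGGATACGTCTCAGAAACATG + B + GTTTAAGAGCTAAGCTG + adaptor3`
and is verified invertible at assembly time (a warning is raised if a
protospacer collides with a constant region).

## Integration barcodes

Barcodes are built by a greedy scan of all `4^L` sequences in
lexicographic order, accepting a candidate iff GC ∈ [0.25, 0.75]
(inclusive at both ends — for 8-mers, 2–6 G/C), no forbidden
substring, and Hamming distance ≥ 4 to every accepted barcode. The
scan is deterministic; `max_n` truncates to a prefix of the full set.
At the default length 8 the scan accepts 234 barcodes, comfortably
above the 215 used in practice; a minimum distance of 4 guarantees
that any single sequencing error is corrected to a unique barcode.
The default forbidden list is the BsmBI site pair, because barcodes
are cloned via BsmBI; this is configurable, and the set size is
unchanged at this scale with or without the exclusion. The cloning
donor is `22-nt arm + reverse-complement(IBC) + 29-nt arm` (59 nt for
8-mers).

## Read counting and recombination

Counting is exact: the first 19 nt of each protospacer is the lookup
key (the sequenced read length), no mismatches are tolerated, and
ambiguous prefixes are a hard error at reference build. Read 2 is
reverse-complemented before lookup by default (`read2_revcomp`), the
conventional orientation for a paired-end read of an inverted
cassette; the simulator shares the flag so the convention is
self-consistent. A pair with both guides found and targeting the same
gene is **matched** and attributed to guide A's element (pairs hitting
the same gene through different elements are counted for both in QC
tallies); both found but different genes is **recombined**; anything
else (including N in a read) is **unmapped**. Control pairs are
compared at element level since all NTCs share one gene label.
Per-sample conservation (matched + recombined + unmapped = reads
processed) is enforced by construction and tested.

Sample indices are matched to the sample sheet with ≤ 1 mismatch
(else `undetermined`); IBC reads are rescued to the whitelist at ≤ 1
mismatch, unique under a distance-4 code, with ambiguous rescues
dropped.

The overall recombination rate is `recombined / (matched +
recombined)` over mapped pairs. The per-element "apparent" rate —
recombined reads involving the element divided by all mapped reads
involving it — is deliberately a *read-level* observable: in a growth
screen it is inflated for strongly depleting elements, whose intact
copies drop out while chimeras carrying a single guide persist. The
simulator reproduces this anticorrelation (tested at r < −0.8).

## Growth phenotypes

`γ = [log₂(RPM_Tf/RPM_T0) − median_NTC log₂(RPM_Tf/RPM_T0)] / doublings`.

Depth normalization is reads-per-million over matched reads per
sample; any uniform rescaling cancels except through the NTC median,
which is subtracted, so γ is invariant to sequencing depth (tested).
The NTC median of returned γ is exactly 0 per replicate. Filters:
zero counts receive a pseudocount of 1 *after* the coverage filter is
evaluated on raw counts; an element is excluded iff some replicate has
< 50 reads at both T0 **and** Tfinal (OR over replicates, AND within
a replicate — the literal reading). Elements filtered in some
replicates contribute their remaining replicates to the mean and are
flagged. Gene-level γ is the unweighted mean over the gene's
unfiltered elements.

Essential-gene recall is a rank-sum (Mann–Whitney U) AUC with midrank
tie handling, scoring by −γ, positives = essential genes at gene
level, negatives = NTC pairs at element level; the implementation is
cross-checked in tests against an exhaustive concordant-pair count
and scikit-learn. Library comparisons use scipy's two-sided
Mann–Whitney with normal approximation, continuity and tie correction
(appropriate at the thousands-of-genes scale this is used for);
percent change is `100·(mean₂ − mean₁)/|mean₁|`. Competitive growth
defect per day is `100 · log₂(ratio_horizon/ratio_day0) / horizon`.

## Knockdown metrics

Perturb-seq knockdown is the fraction of target mRNA remaining:
cells are depth-normalized to 10,000 counts, then the ratio of means
(element cells over NTC cells) is taken for the target gene.
Ratio-of-means on normalized values was chosen over mean-of-ratios
because sparse cells make per-cell ratios unstable (zeros in the
denominator); normalization to a fixed total is the standard
single-cell convention. Cells must carry a single unambiguous
assignment; the assignment model itself is out of scope and consumed
as input. Per-gene summaries are the mean and the maximum knockdown
over the gene's elements ("mean of 3" / "best of 3" for three-element
designs) with library-level medians over genes; best ≥ mean holds by
construction and is tested.

Flow knockdown is
`100 × (1 − (median_target − background)/(median_NTC − background))`,
negative values (up-regulation) reported as-is. The fraction of cells
without evidence of knockdown uses a reference-quantile threshold
(default: the 5th percentile of the NTC intensity distribution;
target cells at or above it are indistinguishable from unperturbed
cells). The exact cut is a convention, exposed as a parameter; note
that with a 5% cut an identical distribution reads ~95%, and a
mixture with non-responder fraction q reads ≈ 0.95·q when knockdown
is otherwise complete.

## Screen simulator

The simulator emulates: (1) a library with one dual-guide element per
gene plus NTC pairs at the configured fraction (deterministic guide
sequences, pairwise-distinct 19-nt prefixes, BsmBI-free); (2)
packaging of **two** genomes drawn i.i.d. from the pool per virion and
one integration per cell — the low-multiplicity-of-infection regime;
with probability `p_switch` a single template switch in the invariant
region joins guide A of genome 1 to guide B of genome 2 (switching is
sequence-independent because the invariant region is ~20× the length
of the variable regions; multi-switch events collapse to the same
observable and are not modeled separately). A switch is *detectable*
iff the genomes differ in gene (or element, for NTCs), so the
expected detectable fraction is `p_switch·(1 − Σf²)` — the package's
closed-form helper, verified by simulation. (3) Growth: abundance
multiplier `2^(γ·doublings)` relative to NTC; chimera fitness
defaults to guide A's gene (single-guide knockdown still occurs) and
can be set to the mean of both genes or to zero — the knob that
reproduces the observation that unrecombined copies of
strong-phenotype elements drop out faster than their chimeras. (4)
Sequencing: multinomial reads at fixed depth per sample; four FASTQ
streams (R1 guide A, R2 guide B reverse-complemented by default, I1
sample index, I2 the integration barcode of the guide-A genome);
constant Q40 qualities; optional uniform substitution errors, off by
default. All randomness derives from the single mandatory seed;
identical configs give byte-identical FASTQ (tested).

**What the simulator does not emulate:** PCR amplification bias,
clonal bottlenecks within an IBC lineage, variable read quality,
indels, multiple integrations per cell, and non-uniform co-packaging.
Passing recovery tests therefore demonstrates correctness of the
estimators under the stated generative model, not robustness to
amplification artifacts or assignment errors in real data.

## Problem sizes and numerical choices

The end-to-end verification runs use 200 genes (20 essential at
γ = −0.3, 6% NTC), 100,000 cells, 10 doublings, and 10⁶ reads per
sample — roughly 470× cell coverage and 4,700× read coverage per
element, a realistic bench-scale screen that keeps the full suite
fast. Recombination recovery is checked at `p_switch = 0.3` on a
uniform 200-element pool against the closed form within 3 binomial
standard errors of the cell count (read-level resampling adds ~10% to
the variance, inside the band). The γ-recovery run sets
`p_switch = 0` because the quantity under test is estimator bias;
recombination handling is exercised separately. Estimator checks use
2·SE bands on ≥ 195 elements; the essential-recall AUC threshold is
0.98. Degenerate inputs are defined rather than left to chance:
all-zero phenotypes map to relative phenotype 0 with a warning; an
empty olfactory null set yields +∞ thresholds; zero mapped reads
yield an undefined (None) recombination rate with a warning; a
missing NTC after filtering is an error since centering is
impossible.

## Known limitations

* Tier-1 ranking uses screens where the gene is a hit (falling back
  to the K562 reference screen when none are recorded); sources
  describing this scheme are ambiguous between K562-only and
  all-hit-screen ranking, and the choice can reorder guides for genes
  essential in many contexts.
* The 19-nt exact-match counter cannot distinguish guides that share
  a 19-nt prefix; such libraries are rejected at reference build
  rather than counted approximately.
* Gene-level significance calling (rank aggregation across elements)
  is out of scope; the package consumes such p-values/FDRs as inputs
  to design and emits per-element statistics from screens.
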