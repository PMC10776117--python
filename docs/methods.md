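# Methods

This note records the models, conventions and numerical choices behind
`csmfr`, and what the synthetic cohorts do and do not establish about real
data.

## Coordinates and data model

Mutations are VCF-native 1-based points; derived regions are 1-based
inclusive intervals with `width = end − start + 1`; annotation tracks are
BED-native 0-based half-open intervals. Conversion happens only in the BED
readers/writers and at the track-query boundary, and both conversions are
involutions (read∘write is the identity on canonical files). A single-base
mutation overlaps a track interval iff its 0-based position falls inside
the half-open interval (≥ 1 bp overlap; no fractional-overlap rule is
used anywhere unless explicitly requested via
`region_recall(min_overlap_fraction=...)`).

## Filtering

The eight retention criteria are applied in a fixed order (PASS flag,
allowed chromosome, SuperDups overlap, VAF, depth, alt reads, population
AF, cohort recurrence) and each rejected call is attributed to its *first*
failed criterion. The attribution order is bookkeeping only: the retained
set is a pure conjunction and therefore independent of both criterion
order and input order (tested). Boundary conventions follow the wording of
the criteria: depth bounds are inclusive ([20, 120]), VAF and population-AF
bounds strict (< 0.5, < 0.01), and "observed less than twice" counts
*distinct individuals* carrying the identical chrom/pos/ref/alt site — a
site seen twice in one individual (e.g. by both callers) still counts
once. A call missing its gnomAD annotation is treated as AF 0: absence
from the population database cannot establish commonness. Multi-allelic
VCF records are split into biallelic candidates on read and non-SNV
alleles discarded. The dual-caller consensus keeps calls whose
(sample, chrom, pos, ref, alt) key appears in both callsets, carrying
depth/AD from the primary caller.

## Cluster detection and classification

A cluster is a maximal run of position-sorted calls on one chromosome in
which every consecutive gap is strictly below the distance threshold
(default 5000 bp), containing at least `min_size` (default 3) calls. This
is consecutive-gap single linkage, *not* a maximum-diameter rule: chains
may span more than the threshold end to end, which is the only reading
consistent with multi-kilobase cluster widths at a 5 kb gap. The
equivalence of chaining with the transitive closure of the pairwise
"< gap" relation on collinear points is exploited by the test oracles
(union-find over all pairs; scipy single-linkage dendrogram cut at
`gap − 1`). Calls from different samples count as distinct members, so a
cluster can in principle be driven by one individual — the leave-one-out
check quantifies exactly this. Clusters are classified by group
composition: YC-only → CSM-FR, CEN-only → CSM-CR, otherwise mixed (kept,
never silently dropped). Regions span the member positions with zero
padding (configurable), clipped to chromosome bounds. The X chromosome is
treated like an autosome throughout, appropriate for a single-sex cohort.

## Randomised-region nulls and exact tests

The null model redraws each observed region once per replicate at a
uniformly random valid start position genome-wide, so the chromosome
choice is weighted by `length − width + 1` and the width multiset is
preserved exactly. No gap/blacklist mask is applied — the null is the
minimal width- and count-matched randomisation; a template-chromosome-
matched variant is available (`chrom_match=True`). Empirical p-values use
add-one smoothing, `p = (1 + #{null ≥ obs}) / (n_reps + 1)` (mirrored for
the lower tail), which is never zero and is super-uniform under the null;
with a discrete statistic the test is conservative, which the calibration
test measures directly. Default 1000 replicates. Fisher's exact tests are
two-sided throughout (scipy, conditional hypergeometric definition with
the standard 1e-7 relative tie tolerance) and report the sample odds
ratio; the test suite verifies agreement with an explicit hypergeometric
tail-sum oracle on every 2×2 table with N ≤ 100, enumerated up to the
p-preserving row/column/transpose symmetries. Deleterious-mutation
enrichment inside CSM-FRs uses a hypergeometric null: replicates draw,
without replacement, as many YC mutations as lie inside the regions and
count how many are damaging.

"Damaging" means CADD PHRED > 15 or FATHMM-MKL class damaging; the two
predictors are also available separately.

## Cohort statistics

Burden comparisons use the Wilcoxon rank-sum test — exact null enumeration
when both groups have ≤ 25 untied observations, tie-corrected normal
approximation with continuity correction otherwise. Burden–age association
is the Pearson correlation with its t-distribution p-value. Partition
tests pool mutation counts across samples into per-group 2×2 tables
(in-category vs out, CEN vs YC) and apply Fisher's exact test per
category; pooling matches the use of count-based exact tests (a per-sample
proportion variant would instead call for a rank test on ratios, which is
what `deleterious_ratio` does for the damaging fraction). The
trinucleotide spectrum maps every SSBS to one of 96 pyrimidine-centric
context classes (6 substitution types × 16 flank pairs), reverse-
complementing purine-reference calls; fractions sum to 1 and the mapping
is invariant under reverse complementation of the reference (tested as an
involution). Reference-allele mismatches against the FASTA are collected
and raised as one error.

## Robustness checks

A reference region is "recovered" if it overlaps any re-detected region by
≥ 1 bp (a minimum overlap fraction is available but defaults to
any-overlap, since no reciprocal-overlap rule is defined for these
analyses). Threshold sensitivity re-runs detection at 3, 4, 6, 8 and 10 kb
and reports recall of the 5 kb reference regions; self-recall at the
reference threshold is exactly 1 by construction. Leave-one-out drops each
individual in turn; exclusion persistence removes a named sample set
(clonal-hematopoiesis carrier status is input metadata, not computed — it
depends on an external curated variant list). Excluding an entire group is
rejected as an error.

## Synthetic cohorts: what they emulate and what they do not

The generator emulates a 73 + 51 two-group blood cohort: ages are normal
(CEN 100.5 ± 3.7 years, YC 60.3 ± 7.8), per-sample background burden is
Poisson and placed uniformly along the genome (chromosome weighted by
length), VAF is Beta(2, 18) per group (mean ≈ 0.1 — a typical blood
somatic VAF scale; the true distribution is unknown, so a flexible bounded
family was chosen), read depth is uniform on [30, 80], and alt-read counts
are binomial in the drawn VAF, clipped so every simulated call passes the
depth/alt-read/VAF filters. YC burden includes a mean-centred +2%/year age
trend so the control group shows the expected positive burden–age
correlation without biasing the group mean. Damaging annotations are
Bernoulli (5% background, 25% inside planted regions) with CADD and
FATHMM set consistently.

Planted structure is the ground truth for detection: mutually disjoint
regions (default 5 YC-only and 7 CEN-only, 3500 bp wide) each receive 4
mutations from *distinct* samples of the relevant group, stratified so all
internal gaps fall below the cluster threshold. Background calls landing
in an opposite-class planted region are resampled out so truth labels stay
unambiguous. Tracks are non-overlapping fixed-width intervals with Poisson
per-chromosome counts placed by the slack construction (coverage is
exactly count × width, giving a closed-form coverage variance for tests);
planted regions can be enriched for a track at a configurable odds ratio
against the closed-form background overlap probability (odds ratio 1
reproduces the background exactly in expectation).

**Problem sizes.** The default genome is three 10 Mb chromosomes and the
default background burden 1 mutation/sample, which keeps the expected
number of spurious (non-planted) distance clusters below 0.1 by the
Poisson-gap calculation — this is what makes exact planted-count recovery
a meaningful check. Burden statistics are instead exercised at the
study-scale 950 vs 881 mutations/sample on the same toy genome (clustering
is not involved there). These sizes keep every oracle brute-forceable.

**Limitations.** The generator does not simulate reads, caller error
models, mutational-signature context biases (spectra are exercised on
uniform-random references only), chromatin- or replication-timing-
dependent mutation rates, shared clonal-hematopoiesis variants, or
linkage between tracks. Passing tests therefore establish correctness of
the algorithms and their conventions — not that real cohorts satisfy the
generative assumptions; on real data the spurious-cluster rate depends on
the true burden density and must be assessed with the robustness module.

## Degenerate inputs and tie-breaks

Zero-depth VAF, empty reference region sets, zero-total Fisher classes,
zero-variance correlations, single-group cohorts and whole-group
exclusions raise `ValueError`; empty mutation sets cluster to empty
results; empty tracks overlap nothing; samples with zero mutations are
included in burden vectors but excluded (with a warning) from per-sample
ratio statistics. All randomness flows from one integer seed through
`numpy.random.SeedSequence` spawning, with per-stage children folded below
2³¹; equal seeds reproduce byte-identical cohorts and pipeline outputs.
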