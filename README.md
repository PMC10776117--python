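# csmfr

Detection and characterisation of **group-exclusive somatic mutation
cluster regions** in two-group blood whole-genome-sequencing cohorts.

Somatic single-base substitutions (SSBSs) accumulate in blood with age, but
they do not land uniformly along the genome. When one group of a cohort —
say, centenarians (CEN) versus younger controls (YC) — shows tight local
clusters of mutations that the other group entirely lacks, those regions
are informative: a region that is recurrently mutated in controls yet
mutation-free in the long-lived group (a *CSM-FR*, centenarian somatic
mutation-free region) may be functionally important enough that damage
there is selected against. The mirror class (CEN-only clusters, *CSM-CRs*)
provides the comparison set. `csmfr` implements the full analysis:

1. **Filtering** — dual-caller consensus plus an eight-criterion SSBS
   filter: PASS flag; autosome/X; outside segmental duplications
   (SuperDups); VAF < 0.5; depth ∈ [20, 120]; ≥ 3 alt reads; gnomAD
   popmax AF < 1%; observed in fewer than two cohort individuals.
2. **Clustering** — a mutation cluster is ≥ 3 calls on one chromosome whose
   consecutive sorted positions are < 5 kb apart (single-linkage chaining);
   clusters are classified CSM-FR (YC-only), CSM-CR (CEN-only) or mixed,
   and converted to genomic regions spanning their members.
3. **Enrichment** — randomised-region null models (width- and
   count-matched redraws, uniform over valid start positions genome-wide)
   with add-one empirical p-values, `p = (1 + #{null ≥ obs}) / (n_reps + 1)`;
   Fisher's exact tests comparing region classes; hypergeometric nulls for
   deleterious-mutation enrichment inside regions (CADD PHRED > 15 or
   FATHMM-MKL damaging).
4. **Cohort statistics** — per-sample burden with Wilcoxon rank-sum group
   comparison, burden–age Pearson correlation, deleterious ratios, pooled
   Fisher tests across genomic partitions, and the 96-class trinucleotide
   mutation spectrum.
5. **Robustness** — distance-threshold sensitivity (3–10 kb), leave-one-out
   recall over individuals, and persistence under exclusion of flagged
   samples (e.g. clonal-hematopoiesis carriers).
6. **Simulation** — a synthetic cohort generator (Poisson background
   burden, Beta-distributed VAF, planted group-exclusive clusters with
   ground-truth labels, annotation tracks with tunable planted enrichment)
   so the whole pipeline is testable without access to restricted human
   data.

## Worked example

```python
from csmfr import (SimulationConfig, simulate_cohort, detect_regions,
                   leave_one_out_recall, permutation_test)
from csmfr.filtering import apply_filters, count_cohort_occurrence, FilterConfig

config = SimulationConfig(seed=42)          # 73 CEN + 51 YC, 5 FR + 7 CR planted
dataset = simulate_cohort(config)
count_cohort_occurrence(dataset.mutations)
kept = apply_filters(
    dataset.mutations,
    FilterConfig(allowed_chroms=frozenset(dataset.genome.names)),
).retained
det = detect_regions(kept)
res = permutation_test(det.fr_regions, dataset.tracks["regulatory"],
                       dataset.genome, n_reps=999, seed=7)
_, loo = leave_one_out_recall(kept, dataset.samples)
```

printing (via the obvious f-strings):

```
cohort: 124 samples, 173 calls
retained after filtering: 173
clusters: 12  CSM-FRs: 5  CSM-CRs: 7
mean CSM-FR width: 2915 bp
regulatory overlap: observed 3/5, null mean 0.57, p = 0.011
leave-one-out recall: 1.00
```

All 12 planted clusters are recovered as the 5 CSM-FRs and 7 CSM-CRs; the
planted regulatory enrichment (odds ratio 8 in the generator) shows up as
3 of 5 CSM-FRs overlapping the track against a null expectation of 0.57
(empirical p ≈ 0.01 at 999 replicates); and because every planted region
has four members from distinct samples, dropping any one individual leaves
every region detectable (leave-one-out recall 1.0).

The same stages are available from the shell:

```bash
csmfr simulate --out cohort/ --seed 42
csmfr run --input-dir cohort/ --out results/ --seed 7
```

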