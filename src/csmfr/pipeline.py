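"""Top-level pipeline: filter -> cluster -> enrich -> stats -> robustness.

Consumes the on-disk layout written by :func:`csmfr.simulate.write_cohort`
(or equivalently structured real inputs), runs the stages in order, writes
every stage's tables plus a provenance copy of the configuration into the
output directory, and returns the collected summary numbers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import clustering, enrichment, io, robustness, stats
from .core import CSM_CR, CSM_FR, GROUP_YC
from .filtering import FilterConfig, apply_filters, count_cohort_occurrence

logger = logging.getLogger("csmfr")


@dataclass
class PipelineConfig:
    input_dir: str
    output_dir: str
    gap_bp: int = clustering.DEFAULT_GAP_BP
    min_size: int = clustering.DEFAULT_MIN_SIZE
    n_reps: int = 1000
    seed: int = 0
    min_depth: int = 20
    max_depth: int = 120
    min_alt_reads: int = 3
    thresholds: tuple[int, ...] = robustness.DEFAULT_THRESHOLDS
    excluded_sample_ids: tuple[str, ...] = ()
    reference_fasta: str | None = None

    def validate(self) -> None:
        if not Path(self.input_dir).is_dir():
            raise FileNotFoundError(f"input directory not found: {self.input_dir}")
        for sub in ("metadata.tsv", "genome.tsv", "vcf"):
            if not (Path(self.input_dir) / sub).exists():
                raise FileNotFoundError(f"missing input: {self.input_dir}/{sub}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the summary dict also written to
    ``summary.json`` in the output directory."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "pipeline_config.json", "w") as fh:
        json.dump(asdict(config), fh, indent=2, default=list)

    from .simulate import read_cohort  # deferred: simulate imports io too

    dataset = read_cohort(config.input_dir)
    genome = dataset.genome
    logger.info("loaded %d calls from %d samples", len(dataset.mutations), len(dataset.samples))

    # --- filtering
    allowed = frozenset(genome.names)
    filter_config = FilterConfig(
        min_depth=config.min_depth,
        max_depth=config.max_depth,
        min_alt_reads=config.min_alt_reads,
        allowed_chroms=allowed,
        superdups=dataset.tracks.get("superdups"),
    )
    count_cohort_occurrence(dataset.mutations)
    filt = apply_filters(dataset.mutations, filter_config)
    io.write_mutations_tsv(filt.retained, out / "mutations_filtered.tsv")
    pd.Series(filt.rejection_counts).rename("rejected").to_csv(
        out / "rejection_counts.tsv", sep="\t"
    )
    logger.info("filtering retained %d / %d calls", len(filt.retained), len(dataset.mutations))

    # --- clustering
    detection = clustering.detect_regions(
        filt.retained, gap_bp=config.gap_bp, min_size=config.min_size, genome=genome
    )
    io.write_bed(detection.fr_regions + detection.cr_regions + detection.mixed_regions,
                 out / "regions.bed")
    summary = {"n_input_calls": len(dataset.mutations),
               "n_retained": len(filt.retained), **detection.summary()}
    logger.info("detected %(n_csm_fr)d CSM-FRs, %(n_csm_cr)d CSM-CRs "
                "(%(n_clusters)d clusters)", summary)

    # --- enrichment
    enrich_rows = []
    if detection.fr_regions:
        for name, track in dataset.tracks.items():
            if name == "superdups":
                continue
            res = enrichment.permutation_test(
                detection.fr_regions, track, genome,
                n_reps=config.n_reps, seed=io.child_seed(config.seed, 10),
            )
            enrich_rows.append({"track": name, "observed": res.observed,
                                "null_mean": float(res.null_values.mean()),
                                "n_reps": res.n_reps, "empirical_p": res.empirical_p})
            if detection.cr_regions:
                odds, p = enrichment.fisher_region_class_comparison(
                    int(res.observed), len(detection.fr_regions),
                    enrichment.count_overlapping_regions(detection.cr_regions, track),
                    len(detection.cr_regions),
                )
                enrich_rows[-1].update({"fr_vs_cr_odds_ratio": odds, "fr_vs_cr_fisher_p": p})
        yc_mutations = [m for m in filt.retained if m.group == GROUP_YC]
        if yc_mutations:
            res = enrichment.deleterious_mutation_enrichment(
                yc_mutations, detection.fr_regions,
                n_reps=config.n_reps, seed=io.child_seed(config.seed, 11),
            )
            enrich_rows.append({"track": "deleterious_yc_mutations",
                                "observed": res.observed,
                                "null_mean": float(res.null_values.mean()),
                                "n_reps": res.n_reps, "empirical_p": res.empirical_p})
    pd.DataFrame(enrich_rows).to_csv(out / "enrichment.tsv", sep="\t", index=False)

    # --- cohort statistics
    summaries, burden_p = stats.burden_summary(filt.retained, dataset.samples)
    summary["burden_mean_cen"] = summaries["CEN"].mean_burden
    summary["burden_mean_yc"] = summaries["YC"].mean_burden
    summary["burden_wilcoxon_p"] = burden_p

    # --- robustness
    if detection.fr_regions:
        sens = robustness.threshold_sensitivity(
            filt.retained, thresholds=config.thresholds,
            reference_gap=config.gap_bp, min_size=config.min_size,
        )
        sens.to_csv(out / "threshold_sensitivity.tsv", sep="\t", index=False)
        loo_table, loo_mean = robustness.leave_one_out_recall(
            filt.retained, dataset.samples, gap_bp=config.gap_bp, min_size=config.min_size
        )
        loo_table.to_csv(out / "leave_one_out.tsv", sep="\t", index=False)
        summary["leave_one_out_mean_recall"] = loo_mean
        if config.excluded_sample_ids:
            summary["exclusion_persistence"] = robustness.exclusion_persistence(
                filt.retained, dataset.samples, config.excluded_sample_ids,
                gap_bp=config.gap_bp, min_size=config.min_size,
            )

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
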