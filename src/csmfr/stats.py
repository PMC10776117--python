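"""Per-sample and per-group cohort statistics.

Covers mutation burden with Wilcoxon rank-sum group comparison, burden/age
Pearson correlation, per-sample deleterious-mutation ratios, pooled Fisher
tests of mutation placement across genomic partitions, and the 96-class
pyrimidine-centric trinucleotide mutation spectrum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pyfaidx import Fasta
from scipy import stats as sps

from .core import GROUP_CEN, GROUP_YC, AnnotationTrack, Mutation

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
PYRIMIDINES = ("C", "T")
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: COSMIC-style ordering of the 96 trinucleotide context classes.
SPECTRUM_CLASSES = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in "ACGT"
    for three in "ACGT"
)


@dataclass
class GroupSummary:
    group: str
    burdens: np.ndarray  # per-sample mutation counts, metadata order
    sample_ids: list[str]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def mean_burden(self) -> float:
        return float(np.mean(self.burdens))


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p.

    Exact null enumeration for small untied samples (both n <= 25),
    tie-corrected normal approximation with continuity correction
    otherwise.
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and x.size <= 25 and y.size <= 25:
        method = "exact"
    else:
        method = "asymptotic"
    return float(
        sps.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def _samples_by_group(metadata: pd.DataFrame) -> dict[str, list[str]]:
    groups: dict[str, list[str]] = {}
    for row in metadata.itertuples(index=False):
        groups.setdefault(row.group, []).append(row.sample_id)
    return groups


def burden_summary(
    mutations: Sequence[Mutation], metadata: pd.DataFrame
) -> tuple[dict[str, GroupSummary], float]:
    """Per-sample burdens per group plus the Wilcoxon rank-sum p between
    groups. Samples with zero calls contribute zero burdens."""
    by_group = _samples_by_group(metadata)
    for g in (GROUP_CEN, GROUP_YC):
        if not by_group.get(g):
            raise ValueError(f"group {g} has no samples")
    counts: dict[str, int] = {sid: 0 for sids in by_group.values() for sid in sids}
    for m in mutations:
        if m.sample_id in counts:
            counts[m.sample_id] += 1
    summaries = {
        g: GroupSummary(
            group=g,
            burdens=np.array([counts[sid] for sid in sids], dtype=float),
            sample_ids=list(sids),
        )
        for g, sids in by_group.items()
    }
    p = wilcoxon_rank_sum(
        summaries[GROUP_CEN].burdens, summaries[GROUP_YC].burdens
    )
    return summaries, p


def burden_age_correlation(
    burdens: Sequence[float], ages: Sequence[float]
) -> tuple[float, float]:
    """Pearson correlation of burden with age (r, t-distribution p)."""
    burdens, ages = np.asarray(burdens, float), np.asarray(ages, float)
    if burdens.size < 3:
        raise ValueError("need at least 3 samples")
    if np.std(burdens) == 0 or np.std(ages) == 0:
        raise ValueError("zero variance in burdens or ages")
    r, p = sps.pearsonr(burdens, ages)
    return float(r), float(p)


def deleterious_ratio(
    mutations: Sequence[Mutation],
    metadata: pd.DataFrame,
    predictor: str = "cadd",
) -> tuple[dict[str, float], pd.DataFrame, float]:
    """Per-sample deleterious fractions and the between-group Wilcoxon p.

    Samples with zero mutations have no defined ratio and are excluded
    with a warning. Returns (per-group mean ratio, per-sample table, p).
    """
    per_sample: dict[str, list[int]] = {}
    for m in mutations:
        tot_del = per_sample.setdefault(m.sample_id, [0, 0])
        tot_del[0] += 1
        tot_del[1] += int(m.is_deleterious(predictor))
    rows = []
    for row in metadata.itertuples(index=False):
        if row.sample_id not in per_sample:
            warnings.warn(f"sample {row.sample_id} has no mutations; ratio undefined")
            continue
        total, n_del = per_sample[row.sample_id]
        rows.append(
            {
                "sample_id": row.sample_id,
                "group": row.group,
                "n_mutations": total,
                "n_deleterious": n_del,
                "ratio": n_del / total,
            }
        )
    table = pd.DataFrame(rows)
    group_means = table.groupby("group")["ratio"].mean().to_dict()
    p = wilcoxon_rank_sum(
        table.loc[table.group == GROUP_CEN, "ratio"],
        table.loc[table.group == GROUP_YC, "ratio"],
    )
    return group_means, table, p


def partition_fisher(
    mutations: Sequence[Mutation],
    partition: AnnotationTrack | Mapping[str, AnnotationTrack],
) -> pd.DataFrame:
    """Pooled per-group Fisher tests of mutation placement in categories.

    For each category the 2x2 table is [[CEN in, CEN out], [YC in, YC out]]
    over pooled mutation counts. A single track is treated as its own
    in/out category; a mapping tests each named category against the rest.
    Empty categories are skipped with a warning.
    """
    if isinstance(partition, AnnotationTrack):
        partition = {partition.name: partition}
    rows = []
    n_by_group = {
        GROUP_CEN: sum(1 for m in mutations if m.group == GROUP_CEN),
        GROUP_YC: sum(1 for m in mutations if m.group == GROUP_YC),
    }
    for name, track in partition.items():
        in_counts = {GROUP_CEN: 0, GROUP_YC: 0}
        for m in mutations:
            if m.group in in_counts and track.covers_point(m.chrom, m.pos):
                in_counts[m.group] += 1
        if in_counts[GROUP_CEN] + in_counts[GROUP_YC] == 0:
            warnings.warn(f"partition category {name!r} contains no mutations; skipped")
            continue
        table = [
            [in_counts[GROUP_CEN], n_by_group[GROUP_CEN] - in_counts[GROUP_CEN]],
            [in_counts[GROUP_YC], n_by_group[GROUP_YC] - in_counts[GROUP_YC]],
        ]
        odds, p = sps.fisher_exact(table, alternative="two-sided")
        rows.append(
            {
                "category": name,
                "cen_in": table[0][0],
                "cen_out": table[0][1],
                "yc_in": table[1][0],
                "yc_out": table[1][1],
                "cen_fraction": table[0][0] / max(n_by_group[GROUP_CEN], 1),
                "yc_fraction": table[1][0] / max(n_by_group[GROUP_YC], 1),
                "odds_ratio": float(odds),
                "fisher_p": float(p),
            }
        )
    return pd.DataFrame(rows)


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))


def spectrum_class(context: str, ref: str, alt: str) -> str:
    """Map one substitution with its trinucleotide context to one of the 96
    pyrimidine-centric classes (purine references are strand-collapsed)."""
    context = context.upper()
    if len(context) != 3 or context[1] != ref:
        raise ValueError(f"context {context!r} does not centre on ref {ref!r}")
    if ref not in PYRIMIDINES:
        context = reverse_complement(context)
        ref = COMPLEMENT[ref]
        alt = COMPLEMENT[alt]
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


def trinucleotide_spectrum(
    mutations: Sequence[Mutation], reference_fasta: str
) -> pd.DataFrame:
    """96-class trinucleotide spectrum (counts and fractions summing to 1).

    Each call's reference allele must match the FASTA base at its position;
    mismatches are collected and reported as a single error.
    """
    fasta = Fasta(reference_fasta)
    counts = {cls: 0 for cls in SPECTRUM_CLASSES}
    mismatches = []
    for m in mutations:
        context = str(fasta[m.chrom][m.pos - 2 : m.pos + 1]).upper()
        if context[1] != m.ref:
            mismatches.append(f"{m.chrom}:{m.pos} ref={m.ref} fasta={context[1]}")
            continue
        counts[spectrum_class(context, m.ref, m.alt)] += 1
    if mismatches:
        raise ValueError(
            "reference allele mismatches with FASTA: " + "; ".join(mismatches[:20])
        )
    total = sum(counts.values())
    df = pd.DataFrame(
        {
            "context": list(SPECTRUM_CLASSES),
            "count": [counts[c] for c in SPECTRUM_CLASSES],
        }
    )
    df["fraction"] = df["count"] / total if total else 0.0
    return df
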