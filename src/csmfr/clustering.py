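"""Distance-based mutation clustering and CSM-FR / CSM-CR classification.

A mutation cluster is three or more calls on one chromosome chained by
consecutive-gap single linkage: after position-sorting, adjacent members are
closer than the gap threshold (default 5 kb, strict inequality). Clusters
whose members all come from younger controls are CSM-FRs (the region is
mutation-free in centenarians); clusters with only centenarian members are
CSM-CRs; the rest are mixed and kept separately rather than discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .core import (
    CSM_CR,
    CSM_FR,
    GROUP_CEN,
    GROUP_YC,
    MIXED,
    GenomeSpec,
    GenomicRegion,
    Mutation,
)

DEFAULT_GAP_BP = 5000
DEFAULT_MIN_SIZE = 3


@dataclass
class MutationCluster:
    chrom: str
    members: list[Mutation]  # position-sorted

    def __post_init__(self) -> None:
        self.members = sorted(self.members, key=lambda m: m.pos)

    @property
    def n_cen(self) -> int:
        return sum(1 for m in self.members if m.group == GROUP_CEN)

    @property
    def n_yc(self) -> int:
        return sum(1 for m in self.members if m.group == GROUP_YC)

    @property
    def cls(self) -> str:
        for m in self.members:
            if m.group not in (GROUP_CEN, GROUP_YC):
                raise ValueError(f"unknown group label {m.group!r}")
        if self.n_cen == 0:
            return CSM_FR
        if self.n_yc == 0:
            return CSM_CR
        return MIXED

    @property
    def samples(self) -> set[str]:
        return {m.sample_id for m in self.members}

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class DetectionResult:
    """Regions and clusters detected in one cohort mutation set."""

    fr_regions: list[GenomicRegion]
    cr_regions: list[GenomicRegion]
    mixed_regions: list[GenomicRegion]
    clusters: list[MutationCluster]

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def mean_width(self, cls: str) -> float:
        regions = {CSM_FR: self.fr_regions, CSM_CR: self.cr_regions, MIXED: self.mixed_regions}[cls]
        if not regions:
            return float("nan")
        return sum(r.width for r in regions) / len(regions)

    def summary(self) -> dict:
        return {
            "n_clusters": self.n_clusters,
            "n_csm_fr": len(self.fr_regions),
            "n_csm_cr": len(self.cr_regions),
            "n_mixed": len(self.mixed_regions),
            "mean_width_fr": self.mean_width(CSM_FR),
            "mean_width_cr": self.mean_width(CSM_CR),
        }


def cluster_mutations(
    mutations: Sequence[Mutation],
    gap_bp: int = DEFAULT_GAP_BP,
    min_size: int = DEFAULT_MIN_SIZE,
) -> list[MutationCluster]:
    """Chain position-sorted calls per chromosome where every consecutive
    gap is strictly below ``gap_bp``; keep maximal runs of >= ``min_size``.

    Calls from different samples at nearby sites each count as one member;
    every call belongs to at most one cluster.
    """
    by_chrom: dict[str, list[Mutation]] = {}
    for m in mutations:
        by_chrom.setdefault(m.chrom, []).append(m)
    clusters: list[MutationCluster] = []
    for chrom in sorted(by_chrom):
        ms = sorted(by_chrom[chrom], key=lambda m: m.pos)
        run: list[Mutation] = [ms[0]]
        for prev, cur in zip(ms, ms[1:]):
            if cur.pos - prev.pos < gap_bp:
                run.append(cur)
            else:
                if len(run) >= min_size:
                    clusters.append(MutationCluster(chrom, run))
                run = [cur]
        if len(run) >= min_size:
            clusters.append(MutationCluster(chrom, run))
    return clusters


def classify_clusters(
    clusters: Sequence[MutationCluster],
) -> tuple[list[MutationCluster], list[MutationCluster], list[MutationCluster]]:
    """Partition clusters into (CSM-FRs, CSM-CRs, mixed) by group makeup."""
    frs = [c for c in clusters if c.cls == CSM_FR]
    crs = [c for c in clusters if c.cls == CSM_CR]
    mixed = [c for c in clusters if c.cls == MIXED]
    return frs, crs, mixed


def cluster_to_region(
    cluster: MutationCluster,
    padding_bp: int = 0,
    genome: GenomeSpec | None = None,
) -> GenomicRegion:
    """Region spanning the member positions, optionally padded and clipped
    to chromosome bounds. Width is end - start + 1 (1-based inclusive)."""
    if not cluster.members:
        raise ValueError("empty cluster")
    start = max(1, cluster.members[0].pos - padding_bp)
    end = cluster.members[-1].pos + padding_bp
    if genome is not None and cluster.chrom in genome:
        end = min(end, genome.length(cluster.chrom))
    return GenomicRegion(cluster.chrom, start, end, cls=cluster.cls)


def detect_regions(
    mutations: Sequence[Mutation],
    gap_bp: int = DEFAULT_GAP_BP,
    min_size: int = DEFAULT_MIN_SIZE,
    padding_bp: int = 0,
    genome: GenomeSpec | None = None,
) -> DetectionResult:
    """Cluster, classify, and convert clusters to regions in one call."""
    clusters = cluster_mutations(mutations, gap_bp=gap_bp, min_size=min_size)
    frs, crs, mixed = classify_clusters(clusters)
    to_region = lambda cs: [cluster_to_region(c, padding_bp, genome) for c in cs]
    return DetectionResult(
        fr_regions=to_region(frs),
        cr_regions=to_region(crs),
        mixed_regions=to_region(mixed),
        clusters=clusters,
    )


def fraction_above_min_size(
    clusters: Sequence[MutationCluster], size: int = DEFAULT_MIN_SIZE
) -> float:
    """Fraction of clusters with strictly more than ``size`` members."""
    if not clusters:
        return float("nan")
    return sum(1 for c in clusters if len(c) > size) / len(clusters)
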