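"""Randomised-region null models and exact tests for region enrichment.

The null model redraws each observed region at a uniformly random valid
start position genome-wide, preserving the width multiset exactly. The
empirical p-value uses add-one smoothing, p = (1 + #{null >= obs}) /
(n_reps + 1), so it is never zero and is super-uniform under the null.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .core import AnnotationTrack, GenomeSpec, GenomicRegion, Mutation


@dataclass
class PermutationResult:
    observed: float
    null_values: np.ndarray
    n_reps: int
    empirical_p: float
    tail: str
    seed: int

    def __post_init__(self) -> None:
        self.null_values = np.asarray(self.null_values)
        if self.null_values.shape != (self.n_reps,):
            raise ValueError("null_values length must equal n_reps")


def empirical_pvalue(observed: float, null_values: np.ndarray, tail: str = "greater") -> float:
    """Add-one empirical p: (1 + #{null at least as extreme}) / (n + 1)."""
    null_values = np.asarray(null_values)
    if tail == "greater":
        extreme = int(np.sum(null_values >= observed))
    elif tail == "less":
        extreme = int(np.sum(null_values <= observed))
    else:
        raise ValueError(f"tail must be 'greater' or 'less', got {tail!r}")
    return (1 + extreme) / (null_values.size + 1)


def _placement_weights(genome: GenomeSpec, width: int) -> tuple[list[str], np.ndarray]:
    chroms = genome.names
    valid = np.array([max(genome.length(c) - width + 1, 0) for c in chroms], dtype=float)
    if valid.sum() == 0:
        raise ValueError(f"no chromosome can hold a region of width {width}")
    return chroms, valid


def sample_random_regions(
    genome: GenomeSpec,
    template_regions: Sequence[GenomicRegion],
    seed: int | np.random.Generator,
    chrom_match: bool = False,
) -> list[GenomicRegion]:
    """One random region per template, preserving each template's width.

    Placement is uniform over all valid start positions genome-wide (so a
    chromosome's chance is proportional to its number of valid starts);
    with ``chrom_match`` each region stays on its template's chromosome.
    Sampled regions may overlap each other.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: list[GenomicRegion] = []
    for template in template_regions:
        w = template.width
        if chrom_match:
            chroms, weights = [template.chrom], np.array(
                [max(genome.length(template.chrom) - w + 1, 0)], dtype=float
            )
            if weights[0] == 0:
                raise ValueError(f"template wider than chromosome {template.chrom}")
        else:
            chroms, weights = _placement_weights(genome, w)
        ci = rng.choice(len(chroms), p=weights / weights.sum())
        start = int(rng.integers(1, genome.length(chroms[ci]) - w + 2))
        out.append(GenomicRegion(chroms[ci], start, start + w - 1, cls=template.cls))
    return out


def count_overlapping_regions(
    regions: Sequence[GenomicRegion], track: AnnotationTrack
) -> int:
    """Number of regions with >= 1 bp overlap with any track interval."""
    if not regions:
        return 0
    return int(track.overlap_flags(list(regions)).sum())


def _null_overlap_counts(
    genome: GenomeSpec,
    widths: Sequence[int],
    track: AnnotationTrack,
    n_reps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorised null: for each replicate, redraw every region uniformly
    and count how many overlap the track."""
    counts = np.zeros(n_reps, dtype=np.int64)
    chrom_names = genome.names
    merged = {c: track.merged(c) for c in chrom_names}
    for w in widths:
        chroms, weights = _placement_weights(genome, w)
        p = weights / weights.sum()
        ci = rng.choice(len(chroms), size=n_reps, p=p)
        lengths = np.array([genome.length(c) for c in chroms], dtype=np.int64)
        starts = 1 + (rng.random(n_reps) * (lengths[ci] - w + 1)).astype(np.int64)
        for k, chrom in enumerate(chroms):
            mask = ci == k
            if not mask.any():
                continue
            t_starts, t_ends = merged[chrom]
            if t_starts.size == 0:
                continue
            s0 = starts[mask] - 1  # half-open
            e0 = s0 + w
            pos = np.searchsorted(t_starts, e0, side="left")
            hit = (pos > 0) & (t_ends[np.maximum(pos - 1, 0)] > s0)
            idx = np.flatnonzero(mask)[hit]
            counts[idx] += 1
    return counts


def permutation_test(
    observed_regions: Sequence[GenomicRegion],
    track: AnnotationTrack,
    genome: GenomeSpec,
    n_reps: int = 1000,
    tail: str = "greater",
    seed: int = 0,
    statistic: Callable[[Sequence[GenomicRegion]], float] | None = None,
) -> PermutationResult:
    """Randomised-region test of a region-set statistic against the track.

    The default statistic is the number of regions overlapping the track;
    a caller-supplied statistic (e.g. disease-mutation coverage) receives
    each replicate's region list. Widths and count are matched exactly.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    if statistic is None:
        observed = float(count_overlapping_regions(observed_regions, track))
        widths = [r.width for r in observed_regions]
        nulls = _null_overlap_counts(genome, widths, track, n_reps, rng).astype(float)
    else:
        observed = float(statistic(observed_regions))
        nulls = np.empty(n_reps, dtype=float)
        for i in range(n_reps):
            nulls[i] = statistic(sample_random_regions(genome, observed_regions, rng))
    return PermutationResult(
        observed=observed,
        null_values=nulls,
        n_reps=n_reps,
        empirical_p=empirical_pvalue(observed, nulls, tail),
        tail=tail,
        seed=seed if isinstance(seed, int) else -1,
    )


def fisher_region_class_comparison(
    n_fr_in: int, n_fr_total: int, n_cr_in: int, n_cr_total: int
) -> tuple[float, float]:
    """Two-sided Fisher's exact test comparing the in-track proportions of
    two region classes. Returns (sample odds ratio, p)."""
    if n_fr_total <= 0 or n_cr_total <= 0:
        raise ValueError("region class totals must be positive")
    if not (0 <= n_fr_in <= n_fr_total and 0 <= n_cr_in <= n_cr_total):
        raise ValueError("counts must lie within totals")
    table = [[n_fr_in, n_fr_total - n_fr_in], [n_cr_in, n_cr_total - n_cr_in]]
    odds_ratio, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds_ratio), float(p)


def dsm_coverage(
    regions: Sequence[GenomicRegion], dsm_positions: Sequence[tuple[str, int]]
) -> tuple[int, int]:
    """(number of disease-susceptibility positions inside any region,
    number of regions containing at least one)."""
    by_chrom: dict[str, np.ndarray] = {}
    for chrom, pos in dsm_positions:
        by_chrom.setdefault(chrom, []).append(pos)  # type: ignore[attr-defined]
    by_chrom = {c: np.sort(np.asarray(p, dtype=np.int64)) for c, p in by_chrom.items()}
    covered = set()
    n_regions_with = 0
    for r in regions:
        pts = by_chrom.get(r.chrom)
        if pts is None:
            continue
        lo = int(np.searchsorted(pts, r.start, side="left"))
        hi = int(np.searchsorted(pts, r.end, side="right"))
        if hi > lo:
            n_regions_with += 1
            covered.update((r.chrom, int(p)) for p in pts[lo:hi])
    return len(covered), n_regions_with


def deleterious_mutation_enrichment(
    yc_mutations: Sequence[Mutation],
    csm_frs: Sequence[GenomicRegion],
    n_reps: int = 1000,
    seed: int = 0,
    predictor: str = "either",
) -> PermutationResult:
    """Are younger-control mutations inside CSM-FRs preferentially damaging?

    Observed: count of deleterious YC mutations inside the regions. Null:
    number deleterious in a uniform without-replacement draw of YC
    mutations of the same size as the in-region set (hypergeometric null).
    """
    rng = np.random.default_rng(seed)
    deleterious = np.array([m.is_deleterious(predictor) for m in yc_mutations])
    in_fr = np.zeros(len(yc_mutations), dtype=bool)
    sorted_frs = sorted(csm_frs, key=lambda r: (r.chrom, r.start))
    fr_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for r in sorted_frs:
        fr_by_chrom.setdefault(r.chrom, ([], []))
        fr_by_chrom[r.chrom][0].append(r.start)  # type: ignore[attr-defined]
        fr_by_chrom[r.chrom][1].append(r.end)  # type: ignore[attr-defined]
    # running max of ends handles possibly overlapping regions
    fr_by_chrom = {
        c: (
            np.asarray(s, dtype=np.int64),
            np.maximum.accumulate(np.asarray(e, dtype=np.int64)),
        )
        for c, (s, e) in fr_by_chrom.items()
    }
    for i, m in enumerate(yc_mutations):
        ivs = fr_by_chrom.get(m.chrom)
        if ivs is None:
            continue
        starts, ends_cummax = ivs
        j = int(np.searchsorted(starts, m.pos, side="right"))
        in_fr[i] = j > 0 and int(ends_cummax[j - 1]) >= m.pos
    sample_size = int(in_fr.sum())
    if sample_size > len(yc_mutations):
        raise ValueError("fewer YC mutations than sample size")
    observed = float(np.sum(deleterious & in_fr))
    if sample_size == 0:
        nulls = np.zeros(n_reps)
    else:
        nulls = np.empty(n_reps)
        n = len(yc_mutations)
        for i in range(n_reps):
            pick = rng.choice(n, size=sample_size, replace=False)
            nulls[i] = deleterious[pick].sum()
    return PermutationResult(
        observed=observed,
        null_values=nulls,
        n_reps=n_reps,
        empirical_p=empirical_pvalue(observed, nulls, "greater"),
        tail="greater",
        seed=seed,
    )
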