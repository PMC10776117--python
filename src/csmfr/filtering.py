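"""Dual-caller consensus and the eight-criterion SSBS filter.

A somatic single-base substitution is retained only if it (1) carries a
PASS filter flag, (2) lies on an autosome or the X chromosome, (3) does not
overlap segmental duplications (SuperDups), (4) has VAF < 0.5, (5) has read
depth in [20, 120], (6) has >= 3 alternative-allele reads, (7) has gnomAD
population allele frequency < 1%, and (8) is observed in fewer than two
cohort individuals. Rejections are attributed to the first failed criterion
in this order, which makes the bookkeeping reproducible while leaving the
retained set order-independent.
"""

from __future__ import annotations

import warnings
from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .core import AnnotationTrack, Mutation

DEFAULT_CHROMS = frozenset(
    {f"chr{i}" for i in range(1, 23)} | {str(i) for i in range(1, 23)} | {"chrX", "X"}
)

#: recognised human chromosome names (either naming style); anything else
#: triggers an unknown-name warning on rejection
KNOWN_CHROMS = DEFAULT_CHROMS | {"chrY", "Y", "chrM", "M", "MT", "chrMT"}

CRITERIA = (
    "pass_flag",
    "allowed_chrom",
    "superdups",
    "vaf",
    "depth",
    "alt_reads",
    "popmax_af",
    "cohort_occurrence",
)


@dataclass
class FilterConfig:
    """Thresholds of the eight retention criteria.

    Depth bounds are inclusive ("not less than ... not more than"); VAF and
    population-AF bounds are strict ("less than"). ``max_cohort_occurrence=1``
    encodes "observed less than twice in the cohort".
    """

    min_depth: int = 20
    max_depth: int = 120
    min_alt_reads: int = 3
    max_vaf: float = 0.5  # exclusive
    max_popmax_af: float = 0.01  # exclusive
    max_cohort_occurrence: int = 1
    allowed_chroms: frozenset[str] = DEFAULT_CHROMS
    superdups: AnnotationTrack | None = None

    def __post_init__(self) -> None:
        if self.min_depth > self.max_depth:
            raise ValueError("min_depth > max_depth")
        if min(self.min_depth, self.min_alt_reads, self.max_vaf, self.max_popmax_af) < 0:
            raise ValueError("thresholds must be nonnegative")


@dataclass
class FilterResult:
    retained: list[Mutation]
    rejection_counts: "OrderedDict[str, int]"

    @property
    def n_rejected(self) -> int:
        return sum(self.rejection_counts.values())


def compute_vaf(alt_reads: int, depth: int) -> float:
    """Variant allele frequency: mutant reads over all mapped reads."""
    if depth <= 0:
        raise ValueError(f"depth must be positive, got {depth}")
    if not 0 <= alt_reads <= depth:
        raise ValueError(f"alt_reads {alt_reads} outside [0, depth={depth}]")
    return alt_reads / depth


def intersect_callsets(
    primary_calls: Iterable[Mutation], confirm_calls: Iterable[Mutation]
) -> list[Mutation]:
    """Calls present in both callers, keyed by (sample, chrom, pos, ref, alt).

    Depth/AD metadata is carried from the primary caller's records.
    """
    confirm_keys = {m.call_key for m in confirm_calls}
    return [m for m in primary_calls if m.call_key in confirm_keys]


def count_cohort_occurrence(mutations: Sequence[Mutation]) -> list[Mutation]:
    """Annotate each call with the number of distinct individuals sharing
    its exact site (chrom, pos, ref, alt)."""
    carriers: dict[tuple, set[str]] = {}
    for m in mutations:
        carriers.setdefault(m.site_key, set()).add(m.sample_id)
    for m in mutations:
        m.cohort_site_count = len(carriers[m.site_key])
    return list(mutations)


def _first_failed_criterion(m: Mutation, config: FilterConfig) -> str | None:
    if m.filter_flag != "PASS":
        return "pass_flag"
    if m.chrom not in config.allowed_chroms:
        if m.chrom not in KNOWN_CHROMS and m.chrom not in config.allowed_chroms:
            warnings.warn(f"unknown chromosome name {m.chrom!r}; rejecting")
        return "allowed_chrom"
    if config.superdups is not None and config.superdups.covers_point(m.chrom, m.pos):
        return "superdups"
    if not m.vaf < config.max_vaf:
        return "vaf"
    if not config.min_depth <= m.depth <= config.max_depth:
        return "depth"
    if m.alt_reads < config.min_alt_reads:
        return "alt_reads"
    popmax = 0.0 if m.popmax_af is None else m.popmax_af
    if not popmax < config.max_popmax_af:
        return "popmax_af"
    count = 1 if m.cohort_site_count is None else m.cohort_site_count
    if count > config.max_cohort_occurrence:
        return "cohort_occurrence"
    return None


def apply_filters(
    mutations: Sequence[Mutation], config: FilterConfig | None = None
) -> FilterResult:
    """Apply the eight retention criteria.

    Returns the retained set plus per-criterion rejection counts (each
    removal attributed to its first failed criterion). Idempotent, and the
    retained set is invariant to input order; missing gnomAD annotation is
    treated as AF 0 (a variant absent from the population database cannot be
    established as common).
    """
    config = config or FilterConfig()
    counts: OrderedDict[str, int] = OrderedDict((c, 0) for c in CRITERIA)
    retained: list[Mutation] = []
    for m in mutations:
        failed = _first_failed_criterion(m, config)
        if failed is None:
            retained.append(m)
        else:
            counts[failed] += 1
    return FilterResult(retained=retained, rejection_counts=counts)
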