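"""Core data model shared across the pipeline stages.

Coordinate conventions
----------------------
Mutations are VCF-native points: 1-based positions. Regions are 1-based
inclusive intervals (``width = end - start + 1``). Annotation tracks are
BED-native: 0-based half-open intervals. Conversion happens only at the
track/region boundary (see :meth:`AnnotationTrack.overlaps_region`) and in
the BED readers/writers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np

GROUP_CEN = "CEN"
GROUP_YC = "YC"
GROUPS = (GROUP_CEN, GROUP_YC)

#: CSM-FR: cluster whose members all come from younger controls (region
#: mutation-free in centenarians). CSM-CR: all members from centenarians.
CSM_FR = "CSM_FR"
CSM_CR = "CSM_CR"
MIXED = "MIXED"

CADD_DAMAGING_THRESHOLD = 15.0
FATHMM_DAMAGING = "damaging"


@dataclass
class Mutation:
    """One somatic single-base substitution call in one individual.

    ``vaf`` is the variant allele frequency, the ratio of reads supporting
    the alternative allele to all mapped reads at the site; it is derived
    from ``alt_reads / depth`` when not given explicitly.
    """

    sample_id: str
    group: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    depth: int
    alt_reads: int
    vaf: float | None = None
    filter_flag: str = "PASS"
    popmax_af: float | None = None  # gnomAD popmax AF; None = absent
    cadd_phred: float | None = None
    fathmm_class: str | None = None  # "damaging" | "nondamaging" | None
    cohort_site_count: int | None = None

    def __post_init__(self) -> None:
        if self.vaf is None:
            if self.depth <= 0:
                raise ValueError(
                    f"depth must be positive to derive VAF, got {self.depth}"
                )
            self.vaf = self.alt_reads / self.depth

    @property
    def site_key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def call_key(self) -> tuple[str, str, int, str, str]:
        return (self.sample_id, self.chrom, self.pos, self.ref, self.alt)

    def is_deleterious(self, predictor: str = "either") -> bool:
        """Damaging status under ``cadd``, ``fathmm`` or ``either``.

        CADD uses the PHRED-scaled score with the conventional >15 damaging
        cutoff; FATHMM-MKL provides a binary class.
        """
        by_cadd = self.cadd_phred is not None and self.cadd_phred > CADD_DAMAGING_THRESHOLD
        by_fathmm = self.fathmm_class == FATHMM_DAMAGING
        if predictor == "cadd":
            return by_cadd
        if predictor == "fathmm":
            return by_fathmm
        if predictor == "either":
            return by_cadd or by_fathmm
        raise ValueError(f"unknown predictor {predictor!r}")

    def copy(self, **changes) -> "Mutation":
        return replace(self, **changes)


@dataclass(frozen=True)
class GenomicRegion:
    """1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int
    cls: str = ""

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid region {self.chrom}:{self.start}-{self.end}")

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicRegion") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def overlap_bp(self, other: "GenomicRegion") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)

    def contains_pos(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


class GenomeSpec:
    """Ordered chromosome names and lengths (bp)."""

    def __init__(self, chromosomes: Sequence[tuple[str, int]] | dict[str, int]):
        if isinstance(chromosomes, dict):
            items = list(chromosomes.items())
        else:
            items = [(str(c), int(l)) for c, l in chromosomes]
        names = [c for c, _ in items]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, length in items:
            if length < 1:
                raise ValueError(f"chromosome {name} has non-positive length")
        self._lengths: dict[str, int] = dict(items)

    @property
    def names(self) -> list[str]:
        return list(self._lengths)

    def length(self, chrom: str) -> int:
        return self._lengths[chrom]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self._lengths)

    @property
    def total_length(self) -> int:
        return sum(self._lengths.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(self._lengths.items())

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GenomeSpec) and self._lengths == other._lengths

    def __repr__(self) -> str:
        return f"GenomeSpec({self._lengths!r})"

    def contains_region(self, region: GenomicRegion) -> bool:
        return region.chrom in self._lengths and region.end <= self._lengths[region.chrom]


class AnnotationTrack:
    """Named set of genomic intervals supporting fast overlap queries.

    Intervals are stored as given (0-based half-open, possibly overlapping);
    a merged, sorted copy per chromosome backs the queries via binary search.
    """

    def __init__(self, name: str, intervals: Iterable[tuple[str, int, int]]):
        self.name = name
        self.intervals: list[tuple[str, int, int]] = []
        for chrom, start, end in intervals:
            start, end = int(start), int(end)
            if end <= start or start < 0:
                raise ValueError(f"invalid interval {chrom}:{start}-{end}")
            self.intervals.append((str(chrom), start, end))
        self.intervals.sort()
        self._merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in self.intervals:
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, ivs in by_chrom.items():
            starts, ends = [], []
            for s, e in ivs:  # already sorted
                if ends and s <= ends[-1]:
                    ends[-1] = max(ends[-1], e)
                else:
                    starts.append(s)
                    ends.append(e)
            self._merged[chrom] = (
                np.asarray(starts, dtype=np.int64),
                np.asarray(ends, dtype=np.int64),
            )

    def __len__(self) -> int:
        return len(self.intervals)

    def merged(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        empty = np.empty(0, dtype=np.int64)
        return self._merged.get(chrom, (empty, empty))

    @property
    def total_coverage(self) -> int:
        """Total merged bases covered."""
        return int(
            sum((ends - starts).sum() for starts, ends in self._merged.values())
        )

    def overlaps_half_open(self, chrom: str, start: int, end: int) -> bool:
        """Does [start, end) (0-based) overlap any interval?"""
        starts, ends = self.merged(chrom)
        if starts.size == 0:
            return False
        idx = int(np.searchsorted(starts, end, side="left"))
        # merged intervals: ends are increasing, so idx-1 has the max end
        return idx > 0 and int(ends[idx - 1]) > start

    def overlaps_region(self, region: GenomicRegion) -> bool:
        return self.overlaps_half_open(region.chrom, region.start - 1, region.end)

    def covers_point(self, chrom: str, pos: int) -> bool:
        """Does the 1-based point fall inside any interval?"""
        return self.overlaps_half_open(chrom, pos - 1, pos)

    def overlap_flags(self, regions: Sequence[GenomicRegion]) -> np.ndarray:
        """Vectorised per-region any-overlap flags."""
        flags = np.zeros(len(regions), dtype=bool)
        by_chrom: dict[str, list[int]] = {}
        for i, r in enumerate(regions):
            by_chrom.setdefault(r.chrom, []).append(i)
        for chrom, idxs in by_chrom.items():
            starts, ends = self.merged(chrom)
            if starts.size == 0:
                continue
            r_start = np.array([regions[i].start - 1 for i in idxs], dtype=np.int64)
            r_end = np.array([regions[i].end for i in idxs], dtype=np.int64)
            pos = np.searchsorted(starts, r_end, side="left")
            hit = (pos > 0) & (ends[np.maximum(pos - 1, 0)] > r_start)
            flags[np.asarray(idxs)] = hit
        return flags
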