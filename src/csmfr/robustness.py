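"""Stability checks on CSM-FR detection.

Three complementary checks: sensitivity of the detected region set to the
clustering distance threshold, leave-one-out recall over individuals, and
persistence of the region set when named samples (e.g. clonal-hematopoiesis
carriers) are excluded. A reference region counts as recovered when it
overlaps a re-detected region by at least one base (a stricter minimum
overlap fraction can be requested).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .clustering import DEFAULT_GAP_BP, DEFAULT_MIN_SIZE, detect_regions
from .core import GenomicRegion, Mutation

DEFAULT_THRESHOLDS = (3000, 4000, 6000, 8000, 10000)


@dataclass
class RecallReport:
    reference_regions: list[GenomicRegion]
    label: str
    hits: np.ndarray  # per-reference-region recovery flags

    @property
    def recall(self) -> float:
        return float(np.mean(self.hits))


def region_recall(
    reference_regions: Sequence[GenomicRegion],
    test_regions: Sequence[GenomicRegion],
    label: str = "",
    min_overlap_fraction: float = 0.0,
) -> RecallReport:
    """Fraction of reference regions recovered in the test set.

    With the default ``min_overlap_fraction=0`` any >=1 bp overlap counts;
    otherwise the overlap must cover at least that fraction of the
    reference region's width.
    """
    reference_regions = list(reference_regions)
    if not reference_regions:
        raise ValueError("reference region set is empty")
    hits = np.zeros(len(reference_regions), dtype=bool)
    for i, ref in enumerate(reference_regions):
        for t in test_regions:
            ov = ref.overlap_bp(t)
            if ov >= 1 and ov >= min_overlap_fraction * ref.width:
                hits[i] = True
                break
    return RecallReport(reference_regions=reference_regions, label=label, hits=hits)


def threshold_sensitivity(
    mutations: Sequence[Mutation],
    thresholds: Sequence[int] = DEFAULT_THRESHOLDS,
    reference_gap: int = DEFAULT_GAP_BP,
    min_size: int = DEFAULT_MIN_SIZE,
) -> pd.DataFrame:
    """Recall of reference-threshold CSM-FRs when re-detected at each
    alternative distance threshold."""
    reference = detect_regions(mutations, gap_bp=reference_gap, min_size=min_size)
    rows = []
    for gap in thresholds:
        test = detect_regions(mutations, gap_bp=gap, min_size=min_size)
        report = region_recall(
            reference.fr_regions, test.fr_regions, label=f"gap={gap}"
        )
        rows.append(
            {
                "gap_bp": gap,
                "n_fr_detected": len(test.fr_regions),
                "recall": report.recall,
            }
        )
    return pd.DataFrame(rows)


def leave_one_out_recall(
    mutations: Sequence[Mutation],
    metadata: pd.DataFrame,
    gap_bp: int = DEFAULT_GAP_BP,
    min_size: int = DEFAULT_MIN_SIZE,
) -> tuple[pd.DataFrame, float]:
    """Drop each individual in turn, re-detect, and report CSM-FR recall
    against the full-cohort regions. Returns (per-sample table, mean)."""
    sample_ids = list(metadata["sample_id"])
    if len(sample_ids) < 2:
        raise ValueError("leave-one-out needs at least 2 samples")
    full = detect_regions(mutations, gap_bp=gap_bp, min_size=min_size)
    if not full.fr_regions:
        raise ValueError("no CSM-FRs detected in the full cohort")
    rows = []
    for sid in sample_ids:
        reduced = [m for m in mutations if m.sample_id != sid]
        redetected = detect_regions(reduced, gap_bp=gap_bp, min_size=min_size)
        report = region_recall(
            full.fr_regions, redetected.fr_regions, label=f"without {sid}"
        )
        rows.append({"excluded_sample": sid, "recall": report.recall})
    table = pd.DataFrame(rows)
    return table, float(table["recall"].mean())


def exclusion_persistence(
    mutations: Sequence[Mutation],
    metadata: pd.DataFrame,
    excluded_sample_ids: Sequence[str],
    gap_bp: int = DEFAULT_GAP_BP,
    min_size: int = DEFAULT_MIN_SIZE,
) -> float:
    """CSM-FR persistence after removing all calls of the excluded samples
    (e.g. clonal-hematopoiesis carriers, supplied as metadata)."""
    excluded = set(excluded_sample_ids)
    known = set(metadata["sample_id"])
    unknown = excluded - known
    if unknown:
        raise ValueError(f"excluded ids not in cohort: {sorted(unknown)}")
    for group, sub in metadata.groupby("group"):
        if set(sub["sample_id"]) <= excluded:
            raise ValueError(f"exclusion removes every sample of group {group}")
    full = detect_regions(mutations, gap_bp=gap_bp, min_size=min_size)
    if not full.fr_regions:
        raise ValueError("no CSM-FRs detected in the full cohort")
    if not excluded:
        return 1.0
    reduced = [m for m in mutations if m.sample_id not in excluded]
    redetected = detect_regions(reduced, gap_bp=gap_bp, min_size=min_size)
    return region_recall(full.fr_regions, redetected.fr_regions).recall
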