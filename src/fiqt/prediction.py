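"""Predicting genome-wide-significant regions in a larger future cohort.

A Z-score's noncentrality grows with the square root of the sample size, so
winner's-curse-adjusted estimates from a discovery cohort, multiplied by
``sqrt(n_ratio)``, are point predictions of the statistics a cohort
``n_ratio`` times larger will see.  Variants whose predicted two-sided
p-value ``2*Phi(-|scaled|)`` falls strictly below the genome-wide threshold
(5e-8 by default) are flagged, and flagged variants within 250 kb of each
other are clumped into regions by single linkage.  Predicted regions can be
intersected with an externally reported locus list, with a user-supplied
special interval (e.g. the extended MHC, chr6:25-33 Mb) tallied separately.

This is a point prediction, not a testing procedure: no error rates attach
to the emitted regions.  Coordinates are 1-based closed internally; BED
output converts to 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import NoncentralityEstimates
from .sumstats import InputError, ScanStatistics

__all__ = [
    "Region",
    "OverlapCounts",
    "GENOME_WIDE_ALPHA",
    "DEFAULT_GAP_BP",
    "scale_noncentrality",
    "predict_significant",
    "cluster_regions",
    "overlap_regions",
    "regions_to_bed",
    "read_interval_list",
]

GENOME_WIDE_ALPHA = 5e-8
DEFAULT_GAP_BP = 250_000


def scale_noncentrality(estimates: NoncentralityEstimates, n_ratio: float) -> NoncentralityEstimates:
    """Project estimates onto a cohort ``n_ratio`` times larger: multiply by sqrt(n_ratio)."""
    if not n_ratio > 0:
        raise ValueError("n_ratio must be positive")
    return replace(estimates, values=estimates.values * np.sqrt(n_ratio))


def predict_significant(scaled: NoncentralityEstimates, alpha: float = GENOME_WIDE_ALPHA):
    """Predicted p-values and the strict-inequality significance mask.

    Returns ``(mask, predicted_p)`` with ``predicted_p = 2*Phi(-|scaled|)``
    and ``mask = predicted_p < alpha`` (a value exactly at the threshold is
    not called significant).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    values = np.asarray(scaled.values, dtype=float)
    predicted_p = 2.0 * stats.norm.sf(np.abs(values))
    mask = predicted_p < alpha
    mask &= ~np.isnan(values)
    return mask, predicted_p


@dataclass(frozen=True)
class Region:
    """A clumped genomic interval of predicted-significant variants."""

    chrom: str
    start_bp: int  # 1-based, closed
    end_bp: int
    lead_variant: str
    min_predicted_p: float
    n_variants: int

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(f"region start {self.start_bp} > end {self.end_bp}")


def cluster_regions(
    stats_table: ScanStatistics,
    mask,
    scaled: NoncentralityEstimates,
    gap_bp: int = DEFAULT_GAP_BP,
) -> list[Region]:
    """Single-linkage clumping of masked variants within ``gap_bp``.

    Consecutive masked variants on the same chromosome whose positions differ
    by at most ``gap_bp`` join one region; region bounds are the member
    min/max positions, the lead variant has the largest |scaled estimate|
    (ties broken by smaller position).
    """
    mask = np.asarray(mask, dtype=bool)
    values = np.asarray(scaled.values, dtype=float)
    if not (len(stats_table) == mask.size == values.size):
        raise InputError("mask and estimates must align with the statistics table")
    chroms = stats_table.chrom
    pos = stats_table.pos_bp
    same_chrom = chroms[1:] == chroms[:-1]
    if np.any(same_chrom & (np.diff(pos) < 0)):
        raise InputError("statistics must be sorted by (chrom, pos)")
    ids = stats_table.variant_ids
    predicted_p = 2.0 * stats.norm.sf(np.abs(values))

    regions: list[Region] = []
    sig = np.flatnonzero(mask)
    if sig.size == 0:
        return regions
    breaks = np.flatnonzero(
        (chroms[sig[1:]] != chroms[sig[:-1]]) | (pos[sig[1:]] - pos[sig[:-1]] > gap_bp)
    )
    for chunk in np.split(sig, breaks + 1):
        strength = np.abs(values[chunk])
        lead = chunk[np.argmax(strength)]  # argmax takes the first max: smaller position
        regions.append(
            Region(
                chrom=str(chroms[chunk[0]]),
                start_bp=int(pos[chunk[0]]),
                end_bp=int(pos[chunk[-1]]),
                lead_variant=str(ids[lead]),
                min_predicted_p=float(predicted_p[chunk].min()),
                n_variants=int(chunk.size),
            )
        )
    return regions


@dataclass(frozen=True)
class OverlapCounts:
    """Intersection tallies of predicted regions against a reported locus list."""

    n_predicted: int
    n_overlapping: int
    n_in_special: int
    n_overlapping_outside_special: int


def _intersects(chrom: str, start: int, end: int, other: tuple) -> bool:
    oc, os, oe = other
    return str(chrom) == str(oc) and start <= int(oe) and int(os) <= end


def overlap_regions(
    predicted: Sequence[Region],
    reported: Sequence[tuple],
    special_interval: tuple | None = None,
) -> OverlapCounts:
    """Count predicted regions overlapping reported loci (closed intervals).

    ``reported`` is a list of (chrom, start_bp, end_bp).  ``special_interval``
    is an optional (chrom, start_bp, end_bp) — e.g. the extended MHC,
    ("6", 25_000_000, 33_000_000) — tallied separately; the
    outside-special count covers regions that overlap a reported locus but
    not the special interval.
    """
    for chrom, start, end in reported:
        if int(start) > int(end):
            raise InputError(f"malformed reported interval {chrom}:{start}-{end}")
    n_overlap = n_special = n_outside = 0
    for region in predicted:
        hit = any(_intersects(region.chrom, region.start_bp, region.end_bp, r) for r in reported)
        in_special = special_interval is not None and _intersects(
            region.chrom, region.start_bp, region.end_bp, special_interval
        )
        n_overlap += hit
        n_special += in_special
        n_outside += hit and not in_special
    return OverlapCounts(
        n_predicted=len(predicted),
        n_overlapping=n_overlap,
        n_in_special=n_special,
        n_overlapping_outside_special=n_outside,
    )


def regions_to_bed(regions: Sequence[Region], path) -> None:
    """Write regions as BED (0-based half-open; start-1, end unchanged)."""
    df = pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.start_bp - 1 for r in regions],
            "end": [r.end_bp for r in regions],
            "name": [r.lead_variant for r in regions],
            "score": [r.min_predicted_p for r in regions],
        }
    )
    df.to_csv(path, sep="\t", index=False, header=False)


def read_interval_list(path) -> list[tuple]:
    """Read (chrom, start, end) intervals from BED (0-based half-open) or
    3-column 1-based text; BED is detected by the ``.bed`` suffix and
    converted to 1-based closed."""
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", engine="python")
    if df.shape[1] < 3:
        raise InputError("interval list needs at least 3 columns: chrom start end")
    is_bed = str(path).endswith(".bed")
    out = []
    for _, row in df.iterrows():
        start = int(row[1]) + 1 if is_bed else int(row[1])
        out.append((str(row[0]), start, int(row[2])))
    return out
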