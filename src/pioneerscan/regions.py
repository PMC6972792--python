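"""Region arithmetic used throughout the pipeline.

These are the interval-level procedures the analysis relies on: merging and
intersecting peak sets, blacklist subtraction, mappability filtering, the
focal-region refinement of ATAC peak regions (intersect, extend by 48 bp,
merge, reduce by 24 bp), window-binned signal annotation, and the
fraction-of-reads-in-peaks (FRIP) library QC statistic.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .intervals import IntervalSet
from .tracks import SignalTrack


def merge_intervals(intervals: IntervalSet, min_gap: int = 0) -> IntervalSet:
    """Union intervals closer than ``min_gap`` bases (0 = touching only)."""
    return intervals.merge(min_gap)


def intersect_intervals(a: IntervalSet, b: IntervalSet, mode: str = "overlap_regions") -> IntervalSet:
    return a.intersect(b, mode=mode)


def resize_intervals(intervals: IntervalSet, delta: int,
                     chrom_sizes: Mapping[str, int] | None = None) -> IntervalSet:
    return intervals.resize(delta, chrom_sizes=chrom_sizes)


def subtract_blacklist(intervals: IntervalSet, blacklist: IntervalSet) -> IntervalSet:
    """Remove every interval overlapping the blacklist by >=1 bp."""
    return intervals.subtract(blacklist)


def refine_atac_regions(small_peaks: IntervalSet, regions: IntervalSet,
                        extend: int = 48, reduce: int = 24,
                        chrom_sizes: Mapping[str, int] | None = None) -> IntervalSet:
    """Refine ATAC regions to focal Tn5-integration hot spots.

    Small, focused peaks are intersected with the original region set, each
    fragment extended by ``extend`` bp on both sides, overlapping fragments
    merged, and the merged intervals reduced by ``reduce`` bp on both sides.
    """
    clipped = small_peaks.intersect(regions, mode="overlap_regions")
    grown = clipped.resize(extend, chrom_sizes=chrom_sizes)
    return grown.merge(0).resize(-reduce, chrom_sizes=chrom_sizes)


def filter_by_track(intervals: IntervalSet, track: SignalTrack, stat: str = "mean",
                    threshold: float = 0.8, keep: str = "ge") -> IntervalSet:
    """Keep intervals whose per-base track statistic passes the comparison.

    Used for the mappability filter (mean mappability >= 0.8 kept; the
    comparison is inclusive on the keep side) and for methylation classing.
    """
    if stat != "mean":
        raise ValueError(f"unsupported stat {stat!r}")
    if keep not in ("ge", "lt"):
        raise ValueError(f"keep must be 'ge' or 'lt', got {keep!r}")
    missing = set(intervals.df["chrom"].unique()) - set(track.data)
    if missing:
        raise KeyError(f"chromosome {sorted(missing)[0]!r} absent from track")
    means = track.set_means(intervals)
    mask = means >= threshold if keep == "ge" else means < threshold
    return intervals.select(mask)


def annotate_window_signal(intervals: IntervalSet, track: SignalTrack,
                           window: int = 200, bin: int = 25) -> np.ndarray:
    """Per-interval binned signal in a center-anchored window.

    Returns a ``len(intervals) x (window // bin)`` matrix of per-bin sums;
    count tracks (library size set) are normalized to tags per 10^7.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if bin <= 0 or window % bin:
        raise ValueError("bin must divide window evenly")
    nbins = window // bin
    centers = intervals.centers()
    chroms = intervals.df["chrom"].to_numpy()
    out = np.zeros((len(intervals), nbins))
    half = window // 2
    for chrom in np.unique(chroms):
        sel = chroms == chrom
        c = centers[sel]
        cols = []
        for j in range(nbins):
            starts = c - half + j * bin
            cols.append(track.interval_sums(chrom, starts, starts + bin))
        out[sel] = np.column_stack(cols)
    return out * track.norm_scale


def frip(reads: SignalTrack, peaks: IntervalSet) -> float:
    """Fraction of reads (tags) falling inside the merged peak set."""
    total = reads.library_size if reads.library_size is not None else reads.total
    if not total or total <= 0:
        raise ValueError("track has zero library size")
    if not len(peaks):
        return 0.0
    inside = reads.set_sums(peaks.merge(0))
    return float(inside.sum() / total)
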