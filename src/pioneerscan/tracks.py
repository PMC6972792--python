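"""Per-base signal tracks (ATAC cuts, ChIP tags, mappability, conservation ...).

A :class:`SignalTrack` holds one dense float array per chromosome. Count
tracks additionally carry a library size (total tags) used for
tags-per-10^7 normalization; ratio/score tracks leave it ``None``.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .intervals import IntervalSet

NORM_FACTOR = 1e7  # tags per 10^7 normalization


class SignalTrack:
    def __init__(self, data: Mapping[str, np.ndarray], library_size: float | None = None):
        self.data = {c: np.asarray(a, dtype=float) for c, a in data.items()}
        for chrom, arr in self.data.items():
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite values on {chrom}")
        if library_size is not None and library_size <= 0:
            raise ValueError("library size must be positive")
        self.library_size = library_size

    # -- construction ------------------------------------------------------

    @classmethod
    def zeros(cls, chrom_sizes: Mapping[str, int], library_size: float | None = None):
        return cls({c: np.zeros(n) for c, n in chrom_sizes.items()}, library_size)

    @classmethod
    def from_counts(cls, data: Mapping[str, np.ndarray]) -> "SignalTrack":
        """Count track whose library size is the total number of tags."""
        total = float(sum(np.asarray(a).sum() for a in data.values()))
        return cls(data, library_size=total if total > 0 else None)

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(a) for c, a in self.data.items()}

    @property
    def total(self) -> float:
        return float(sum(a.sum() for a in self.data.values()))

    @property
    def norm_scale(self) -> float:
        """Multiplier converting raw tags to tags per 10^7."""
        if self.library_size is None:
            return 1.0
        return NORM_FACTOR / self.library_size

    def __getitem__(self, chrom: str) -> np.ndarray:
        if chrom not in self.data:
            raise KeyError(f"chromosome {chrom!r} absent from track")
        return self.data[chrom]

    # -- interval statistics ----------------------------------------------

    def interval_sums(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        arr = self[chrom]
        csum = np.concatenate([[0.0], np.cumsum(arr)])
        s = np.clip(np.asarray(starts, dtype=int), 0, len(arr))
        e = np.clip(np.asarray(ends, dtype=int), 0, len(arr))
        e = np.maximum(e, s)
        return csum[e] - csum[s]

    def set_sums(self, intervals: IntervalSet) -> np.ndarray:
        """Raw sum over each interval, in the set's row order."""
        out = np.zeros(len(intervals))
        df = intervals.df
        for chrom in df["chrom"].unique():
            sel = (df["chrom"] == chrom).to_numpy()
            out[sel] = self.interval_sums(
                chrom, df.loc[sel, "start"].to_numpy(), df.loc[sel, "end"].to_numpy()
            )
        return out

    def set_means(self, intervals: IntervalSet) -> np.ndarray:
        widths = (intervals.df["end"] - intervals.df["start"]).to_numpy(dtype=float)
        return self.set_sums(intervals) / widths

    def window_sums(self, chrom: str, centers: np.ndarray, window: int) -> np.ndarray:
        """Raw sums in ``window``-bp windows centered on ``centers``."""
        half = window // 2
        centers = np.asarray(centers, dtype=int)
        return self.interval_sums(chrom, centers - half, centers - half + window)

    def profile(self, chrom: str, center: int, flank: int, reverse: bool = False) -> np.ndarray:
        """Per-base values over ``[center-flank, center+flank]`` (length 2*flank+1),
        zero-padded at chromosome ends; reversed for minus-strand anchors."""
        arr = self[chrom]
        lo, hi = center - flank, center + flank + 1
        out = np.zeros(2 * flank + 1)
        s, e = max(lo, 0), min(hi, len(arr))
        if e > s:
            out[s - lo : s - lo + (e - s)] = arr[s:e]
        return out[::-1] if reverse else out
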