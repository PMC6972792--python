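"""Genomic intervals and interval-set arithmetic.

All coordinates are 0-based half-open ``[start, end)`` — the BED convention.
An :class:`IntervalSet` is a thin wrapper around a :class:`pandas.DataFrame`
with at least the columns ``chrom``, ``start``, ``end``; any further columns
(name, score, strand, normalized tag counts, flags ...) are carried through
every operation that keeps rows intact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

CORE_COLUMNS = ("chrom", "start", "end")


@dataclass(frozen=True)
class GenomicInterval:
    """A single 0-based half-open genomic interval.

    ``strand`` is one of ``'+'``, ``'-'`` or ``'.'`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class IntervalSet:
    """An ordered collection of genomic intervals with per-interval attributes."""

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        if validate:
            missing = [c for c in CORE_COLUMNS if c not in df.columns]
            if missing:
                raise ValueError(f"missing required columns: {missing}")
            if len(df):
                if (df["start"] < 0).any():
                    raise ValueError("negative start coordinate")
                if (df["end"] <= df["start"]).any():
                    raise ValueError("empty or inverted interval")
        self.df = df.reset_index(drop=True)

    # -- construction ------------------------------------------------------

    @classmethod
    def empty(cls, extra_columns: Iterable[str] = ()) -> "IntervalSet":
        cols = list(CORE_COLUMNS) + list(extra_columns)
        df = pd.DataFrame({c: [] for c in cols})
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
        return cls(df, validate=False)

    @classmethod
    def from_records(cls, records, columns: Iterable[str] = CORE_COLUMNS) -> "IntervalSet":
        if not records:
            return cls.empty(c for c in columns if c not in CORE_COLUMNS)
        return cls(pd.DataFrame.from_records(records, columns=list(columns)))

    @classmethod
    def from_intervals(cls, intervals: Iterable[GenomicInterval]) -> "IntervalSet":
        recs = [(iv.chrom, iv.start, iv.end, iv.strand) for iv in intervals]
        return cls.from_records(recs, columns=["chrom", "start", "end", "strand"])

    # -- basics ------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[GenomicInterval]:
        for row in self.df.itertuples(index=False):
            strand = getattr(row, "strand", ".")
            if strand not in ("+", "-"):
                strand = "."
            yield GenomicInterval(row.chrom, int(row.start), int(row.end), strand)

    @property
    def total_length(self) -> int:
        if not len(self.df):
            return 0
        return int((self.df["end"] - self.df["start"]).sum())

    def sort(self) -> "IntervalSet":
        df = self.df.sort_values(["chrom", "start", "end"], kind="mergesort")
        return IntervalSet(df, validate=False)

    def centers(self) -> np.ndarray:
        return ((self.df["start"].to_numpy() + self.df["end"].to_numpy()) // 2).astype(int)

    def select(self, mask) -> "IntervalSet":
        return IntervalSet(self.df.loc[np.asarray(mask)], validate=False)

    def with_column(self, name: str, values) -> "IntervalSet":
        df = self.df.copy()
        df[name] = values
        return IntervalSet(df, validate=False)

    # -- arithmetic --------------------------------------------------------

    def merge(self, min_gap: int = 0) -> "IntervalSet":
        """Union intervals whose gap is smaller than ``min_gap``.

        Attribute columns are dropped (a merged interval has no single parent).
        """
        if min_gap < 0:
            raise ValueError(f"min_gap must be >= 0, got {min_gap}")
        if not len(self.df):
            return IntervalSet.empty()
        out_chrom, out_start, out_end = [], [], []
        for chrom, grp in self.sort().df.groupby("chrom", sort=True):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            cur_s, cur_e = int(starts[0]), int(ends[0])
            for s, e in zip(starts[1:], ends[1:]):
                if s - cur_e < min_gap or s < cur_e:
                    cur_e = max(cur_e, int(e))
                else:
                    out_chrom.append(chrom)
                    out_start.append(cur_s)
                    out_end.append(cur_e)
                    cur_s, cur_e = int(s), int(e)
            out_chrom.append(chrom)
            out_start.append(cur_s)
            out_end.append(cur_e)
        return IntervalSet(
            pd.DataFrame({"chrom": out_chrom, "start": out_start, "end": out_end}),
            validate=False,
        )

    def _overlap_mask(self, other: "IntervalSet") -> np.ndarray:
        """Boolean per-row mask: does this row overlap >=1 bp of ``other``."""
        mask = np.zeros(len(self.df), dtype=bool)
        if not len(self.df) or not len(other):
            return mask
        merged = other.merge(0).df
        by_chrom = {c: g for c, g in merged.groupby("chrom")}
        chroms = self.df["chrom"].to_numpy()
        starts = self.df["start"].to_numpy()
        ends = self.df["end"].to_numpy()
        for chrom in np.unique(chroms):
            g = by_chrom.get(chrom)
            if g is None:
                continue
            bs = g["start"].to_numpy()
            be = g["end"].to_numpy()
            sel = chroms == chrom
            # candidate merged interval: last one starting before the query end
            idx = np.searchsorted(bs, ends[sel], side="left") - 1
            ok = idx >= 0
            hit = np.zeros(ok.shape, dtype=bool)
            hit[ok] = be[idx[ok]] > starts[sel][ok]
            mask[sel] = hit
        return mask

    def intersect(self, other: "IntervalSet", mode: str = "overlap_regions") -> "IntervalSet":
        """Intersect with ``other``.

        ``overlap_regions`` returns the clipped pairwise intersections (against
        the merged form of ``other``); ``a_with_any_overlap`` returns the rows
        of *this* set overlapping >=1 bp of ``other``, attributes intact.
        """
        if mode == "a_with_any_overlap":
            return self.select(self._overlap_mask(other))
        if mode != "overlap_regions":
            raise ValueError(f"unknown mode {mode!r}")
        if not len(self.df) or not len(other):
            return IntervalSet.empty()
        merged = other.merge(0).df
        by_chrom = {c: g for c, g in merged.groupby("chrom")}
        out = []
        for row in self.df.itertuples(index=False):
            g = by_chrom.get(row.chrom)
            if g is None:
                continue
            bs = g["start"].to_numpy()
            be = g["end"].to_numpy()
            lo = np.searchsorted(be, row.start, side="right")
            hi = np.searchsorted(bs, row.end, side="left")
            for j in range(lo, hi):
                s = max(row.start, int(bs[j]))
                e = min(row.end, int(be[j]))
                if e > s:
                    out.append((row.chrom, s, e))
        return IntervalSet.from_records(out)

    def subtract(self, blacklist: "IntervalSet") -> "IntervalSet":
        """Drop every interval overlapping ``blacklist`` by >=1 bp."""
        return self.select(~self._overlap_mask(blacklist))

    def resize(self, delta: int, chrom_sizes: Mapping[str, int] | None = None) -> "IntervalSet":
        """Grow (positive ``delta``) or shrink each interval by ``delta`` on
        both sides, clipping at chromosome ends; degenerate intervals drop."""
        if not len(self.df):
            return IntervalSet(self.df.copy(), validate=False)
        df = self.df.copy()
        df["start"] = df["start"] - delta
        df["end"] = df["end"] + delta
        df["start"] = df["start"].clip(lower=0)
        if chrom_sizes is not None:
            limits = df["chrom"].map(chrom_sizes)
            if limits.isna().any():
                bad = df.loc[limits.isna(), "chrom"].iloc[0]
                raise KeyError(f"chromosome {bad!r} absent from chrom_sizes")
            df["end"] = np.minimum(df["end"], limits.astype(int))
        df = df[df["end"] > df["start"]]
        return IntervalSet(df, validate=False)

    # -- coverage ----------------------------------------------------------

    def coverage_array(self, chrom: str, length: int) -> np.ndarray:
        """Boolean per-base coverage of one chromosome (testing aid)."""
        cov = np.zeros(length, dtype=bool)
        g = self.df[self.df["chrom"] == chrom]
        for s, e in zip(g["start"], g["end"]):
            cov[max(0, int(s)) : min(length, int(e))] = True
        return cov
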