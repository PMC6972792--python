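"""Plain-text genomics I/O: BED3/BED6(+), bedGraph, FASTA, PWM files.

The package exchanges data exclusively in uncompressed text formats; dense
tracks round-trip through bedGraph (``chrom  start  end  value``).
"""

from __future__ import annotations

import os
from typing import Mapping

import numpy as np
import pandas as pd

from .intervals import IntervalSet
from .tracks import SignalTrack

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


# -- BED ------------------------------------------------------------------


def read_bed(path: str) -> IntervalSet:
    """Read BED3/BED6+ (tab-separated, no header)."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return IntervalSet.empty()
    ncol = df.shape[1]
    names = BED6_COLUMNS[: min(ncol, 6)] + [f"extra{i}" for i in range(max(0, ncol - 6))]
    df.columns = names
    return IntervalSet(df)


def write_bed(intervals: IntervalSet, path: str, columns: list[str] | None = None) -> None:
    df = intervals.df
    if columns is None:
        columns = [c for c in BED6_COLUMNS if c in df.columns]
        columns += [c for c in df.columns if c not in columns]
    out = df.copy()
    if "name" in columns and "name" not in out.columns:
        out["name"] = "."
    if "score" in columns and "score" not in out.columns:
        out["score"] = 0
    if "strand" in columns and "strand" not in out.columns:
        out["strand"] = "."
    out[columns].to_csv(path, sep="\t", header=False, index=False)


# -- bedGraph -------------------------------------------------------------


def read_bedgraph(path: str, chrom_sizes: Mapping[str, int],
                  library_size: float | None = None) -> SignalTrack:
    data = {c: np.zeros(n) for c, n in chrom_sizes.items()}
    try:
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "value"], comment="#")
    except pd.errors.EmptyDataError:
        return SignalTrack(data, library_size)
    for row in df.itertuples(index=False):
        if row.chrom not in data:
            raise KeyError(f"chromosome {row.chrom!r} not in chrom_sizes")
        data[row.chrom][int(row.start): int(row.end)] = row.value
    return SignalTrack(data, library_size)


def write_bedgraph(track: SignalTrack, path: str) -> None:
    """Run-length encode each chromosome; zero runs are omitted."""
    with open(path, "w") as fh:
        for chrom in sorted(track.data):
            arr = track.data[chrom]
            if not len(arr):
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(arr)]])
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


# -- FASTA ----------------------------------------------------------------


def read_fasta(path: str) -> dict[str, str]:
    """Read a (small) FASTA file into a dict of upper-case sequences."""
    genome: dict[str, str] = {}
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    genome[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line.upper())
    if name is not None:
        genome[name] = "".join(chunks)
    return genome


def write_fasta(genome: Mapping[str, str], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
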