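"""Tn5 cut processing, accessibility clustering and footprints.

Covers the accessibility arm of the analysis: shifting read ends to the Tn5
binding site (+4 / -5), building peak-centered pre/post cut-count matrices,
K-means clustering of peaks by accessibility with a deterministic ordering
and a per-cluster remodeling index, and single-bp motif-centered footprint
profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .intervals import IntervalSet
from .tracks import SignalTrack


def tn5_shift(read_start: int, read_end: int, strand: str) -> int:
    """Cut position of one read end: plus-strand reads cut at start+4,
    minus-strand reads at end-5 (half-open coordinates)."""
    if read_end <= read_start:
        raise ValueError("read end must exceed start")
    if strand == "+":
        return read_start + 4
    if strand == "-":
        return read_end - 5
    raise ValueError(f"invalid strand {strand!r}")


def cuts_from_fragments(fragments: pd.DataFrame, chrom_sizes: dict[str, int]) -> SignalTrack:
    """Build a cut-site track from paired fragments (chrom, start, end):
    each fragment contributes exactly two cuts, one per end."""
    data = {c: np.zeros(n) for c, n in chrom_sizes.items()}
    for row in fragments.itertuples(index=False):
        arr = data[row.chrom]
        for cut in (tn5_shift(row.start, row.end, "+"), tn5_shift(row.start, row.end, "-")):
            if 0 <= cut < len(arr):
                arr[cut] += 1
    return SignalTrack.from_counts(data)


def peak_count_matrix(peaks: IntervalSet, pre: SignalTrack, post: SignalTrack,
                      window: int = 300) -> np.ndarray:
    """Normalized (tags per 10^7) cut counts in peak-centered windows;
    column 0 = pre-induction, column 1 = post-induction."""
    centers = peaks.centers()
    chroms = peaks.df["chrom"].to_numpy()
    out = np.zeros((len(peaks), 2))
    for j, track in enumerate((pre, post)):
        for chrom in np.unique(chroms):
            sel = chroms == chrom
            out[sel, j] = track.window_sums(chrom, centers[sel], window)
        out[:, j] *= track.norm_scale
    return out


def remodeling_index(pre, post):
    """Signed accessibility change: log2((post + 1) / (pre + 1)) of
    normalized window counts. Zero means no remodeling; the +1 pseudocount
    keeps the index symmetric and bounded near zero change."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if (pre < 0).any() or (post < 0).any():
        raise ValueError("counts must be non-negative")
    return np.log2((post + 1.0) / (pre + 1.0))


@dataclass
class ClusterModel:
    """Peak->cluster assignment ordered by increasing pre-induction
    accessibility, with per-cluster summaries."""

    K: int
    labels: np.ndarray  # 1..K per peak
    summary: pd.DataFrame  # index: cluster id; mean_pre, mean_post, rem_index, n
    seed: int

    def cluster_of(self, i: int) -> int:
        return int(self.labels[i])


def cluster_peaks(matrix: np.ndarray, K: int = 14, seed: int = 0,
                  n_init: int = 10, log_transform: bool = True) -> ClusterModel:
    """K-means clustering of the peaks x (pre, post) accessibility matrix.

    Counts are log2(x+1)-transformed before clustering; the best of
    ``n_init`` restarts (by inertia) is kept and clusters are relabeled
    1..K by increasing mean pre-induction accessibility.
    """
    matrix = np.asarray(matrix, dtype=float)
    if K < 1:
        raise ValueError("K must be >= 1")
    if matrix.shape[0] < K:
        raise ValueError(f"{matrix.shape[0]} rows < K={K}")
    X = np.log2(matrix + 1.0) if log_transform else matrix
    km = KMeans(n_clusters=K, n_init=n_init, random_state=seed)
    raw = km.fit_predict(X)
    # order clusters by mean pre-induction accessibility (column 0)
    order = np.argsort(
        [matrix[raw == k, 0].mean() for k in range(K)], kind="stable"
    )
    relabel = np.empty(K, dtype=int)
    relabel[order] = np.arange(1, K + 1)
    labels = relabel[raw]
    rows = []
    for k in range(1, K + 1):
        sel = labels == k
        mp, mq = matrix[sel, 0].mean(), matrix[sel, 1].mean()
        rows.append(
            {
                "cluster": k,
                "n": int(sel.sum()),
                "mean_pre": mp,
                "mean_post": mq,
                "rem_index": float(np.mean(remodeling_index(matrix[sel, 0], matrix[sel, 1]))),
            }
        )
    summary = pd.DataFrame(rows).set_index("cluster")
    return ClusterModel(K=K, labels=labels, summary=summary, seed=seed)


def footprint_profile(matches: IntervalSet, cuts: SignalTrack,
                      flank: int = 100) -> pd.DataFrame:
    """Mean per-bp normalized cut count around motif centers.

    Windows are strand-oriented (minus-strand motifs reversed) and span
    ``[-flank, +flank]``; the profile is the per-motif average, normalized
    to tags per 10^7. Returns a two-column frame (offset, value).
    """
    if not len(matches):
        raise ValueError("empty match set")
    total = np.zeros(2 * flank + 1)
    df = matches.df
    strands = df["strand"].to_numpy() if "strand" in df.columns else ["+"] * len(df)
    centers = matches.centers()
    for chrom, center, strand in zip(df["chrom"], centers, strands):
        total += cuts.profile(chrom, int(center), flank, reverse=strand == "-")
    values = total / len(matches) * cuts.norm_scale
    return pd.DataFrame({"offset": np.arange(-flank, flank + 1), "value": values})
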