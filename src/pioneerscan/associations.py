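"""Motif co-association and homotypic-pair statistics.

Covers reduction of discovered PWMs to named motif classes by matrix
correlation, per-peak motif-class co-occurrence matrices and networks,
homotypic pair enumeration (max distance 150 bp, keeping orientation,
distance and scores), single-motif definition, and exact hypergeometric
enrichment of pair distances in the bound fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import IntervalSet
from .motifs import PWM

PAIR_MAX_DIST = 150
REPORT_BAND = (12, 50)  # bp range enriched among bound pairs


@dataclass
class MotifClass:
    name: str
    representative: PWM
    members: list[PWM] = field(default_factory=list)
    correlations: list[float] = field(default_factory=list)


def pwm_correlation(a: PWM, b: PWM) -> float:
    """Best Pearson correlation of flattened aligned probability matrices
    over all offsets (up to half the shorter width) and both orientations."""
    best = -1.0
    max_shift = min(a.width, b.width) // 2
    for cand in (b, b.reverse_complement()):
        for shift in range(-max_shift, max_shift + 1):
            lo_a = max(0, shift)
            hi_a = min(a.width, cand.width + shift)
            if hi_a - lo_a < 4:
                continue
            pa = a.probs[lo_a:hi_a].ravel()
            pb = cand.probs[lo_a - shift : hi_a - shift].ravel()
            if pa.std() == 0 or pb.std() == 0:
                continue
            r = float(np.corrcoef(pa, pb)[0, 1])
            best = max(best, r)
    return best


def reduce_to_classes(pwms: list[PWM], known: dict[str, list[PWM]],
                      r_threshold: float = 0.85) -> list[MotifClass]:
    """Assign each PWM to the class of its best-correlated known motif if the
    correlation exceeds ``r_threshold``; unmatched PWMs are dropped."""
    classes: dict[str, MotifClass] = {}
    for pwm in pwms:
        best_r, best_class = -1.0, None
        for cls_name, members in known.items():
            for ref in members:
                r = pwm_correlation(pwm, ref)
                if r > best_r:
                    best_r, best_class = r, (cls_name, ref)
        if best_class is not None and best_r > r_threshold:
            cls_name, ref = best_class
            if cls_name not in classes:
                classes[cls_name] = MotifClass(name=cls_name, representative=ref)
            classes[cls_name].members.append(pwm)
            classes[cls_name].correlations.append(best_r)
    return list(classes.values())


def peak_class_matrix(peaks: IntervalSet, anchor_matches: IntervalSet,
                      class_matches: dict[str, IntervalSet],
                      min_dist_co: int = 4, min_dist_self: int = 6) -> pd.DataFrame:
    """Per-peak motif-class presence and anchor-motif count.

    The anchor is the best-scoring (ties: leftmost) focal-factor match in the
    peak. A class is present iff >= 1 member instance lies inside the peak
    with center >= ``min_dist_co`` bp from the anchor center. The focal-motif
    count keeps matches pairwise >= ``min_dist_self`` apart (greedy
    left-to-right). Peaks without an anchor get zero rows.
    """
    cols = sorted(class_matches) + ["anchor_count"]
    out = pd.DataFrame(0, index=range(len(peaks)), columns=cols)
    a_df = anchor_matches.df
    cls_centers = {
        name: (
            m.df["chrom"].to_numpy(),
            ((m.df["start"].to_numpy() + m.df["end"].to_numpy()) // 2),
        )
        for name, m in class_matches.items()
    }
    a_centers = (a_df["start"].to_numpy() + a_df["end"].to_numpy()) // 2
    a_scores = a_df["score"].to_numpy() if "score" in a_df.columns else np.zeros(len(a_df))
    a_chrom = a_df["chrom"].to_numpy()
    for i, row in enumerate(peaks.df.itertuples(index=False)):
        in_peak = (a_chrom == row.chrom) & (a_centers >= row.start) & (a_centers < row.end)
        idx = np.flatnonzero(in_peak)
        if not len(idx):
            continue
        # anchor: highest score, leftmost tie-break
        best = idx[np.lexsort((a_centers[idx], -a_scores[idx]))[0]]
        anchor_center = a_centers[best]
        for name, (cc, cpos) in cls_centers.items():
            hit = (cc == row.chrom) & (cpos >= row.start) & (cpos < row.end)
            if np.any(np.abs(cpos[hit] - anchor_center) >= min_dist_co):
                out.loc[i, name] = 1
        # greedy left-to-right count with min self-distance
        count, last = 0, None
        for c in np.sort(a_centers[idx]):
            if last is None or c - last >= min_dist_self:
                count += 1
                last = c
        out.loc[i, "anchor_count"] = count
    return out


def build_network(matrix: pd.DataFrame, anchor_label: str = "PU.1x2"):
    """Node sizes and edge widths as fractions of all peaks.

    Nodes: per class, the fraction of peaks containing it, plus a second
    focal-factor node = fraction of peaks with >= 2 focal motifs. Edges: for
    each node pair, the fraction of peaks containing both.
    """
    if not len(matrix):
        raise ValueError("empty co-occurrence matrix")
    binary = matrix.drop(columns=["anchor_count"]).astype(bool)
    binary[anchor_label] = matrix["anchor_count"] >= 2
    n = len(binary)
    nodes = {c: float(binary[c].sum()) / n for c in binary.columns}
    edges = {}
    cols = sorted(binary.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            edges[(a, b)] = float((binary[a] & binary[b]).sum()) / n
    return nodes, edges


def enumerate_pairs(matches: IntervalSet, max_dist: int = PAIR_MAX_DIST) -> pd.DataFrame:
    """All homotypic pairs with 5'-start distance in [1, max_dist].

    Distance is the difference of start coordinates on the reference strand
    (so >= 12 means two 12-mers cannot overlap); orientation is ``same`` or
    ``opposite`` by strand agreement; member a precedes b in genome order.
    """
    df = matches.df.sort_values(["chrom", "start"], kind="mergesort").reset_index()
    starts = df["start"].to_numpy()
    chroms = df["chrom"].to_numpy()
    strands = df["strand"].to_numpy() if "strand" in df.columns else np.full(len(df), "+")
    scores = df["score"].to_numpy() if "score" in df.columns else np.zeros(len(df))
    rows = []
    for i in range(len(df)):
        j = i + 1
        while j < len(df) and chroms[j] == chroms[i] and starts[j] - starts[i] <= max_dist:
            d = int(starts[j] - starts[i])
            if d >= 1:
                rows.append(
                    (
                        chroms[i], int(starts[i]), int(starts[j]), d,
                        "same" if strands[i] == strands[j] else "opposite",
                        float(scores[i]), float(scores[j]),
                        int(df["index"][i]), int(df["index"][j]),
                    )
                )
            j += 1
    return pd.DataFrame(
        rows,
        columns=["chrom", "start_a", "start_b", "distance", "orientation",
                 "score_a", "score_b", "idx_a", "idx_b"],
    )


def single_motifs(matches: IntervalSet, max_dist: int = PAIR_MAX_DIST) -> IntervalSet:
    """Matches lacking any neighboring match within ``max_dist`` bp."""
    df = matches.df.sort_values(["chrom", "start"], kind="mergesort")
    idx = df.index.to_numpy()
    chroms = df["chrom"].to_numpy()
    starts = df["start"].to_numpy()
    has_neighbor = np.zeros(len(df), dtype=bool)
    for i in range(1, len(df)):
        if chroms[i] == chroms[i - 1] and starts[i] - starts[i - 1] <= max_dist:
            has_neighbor[i] = has_neighbor[i - 1] = True
    keep = np.zeros(len(matches), dtype=bool)
    keep[idx[~has_neighbor]] = True
    return matches.select(keep)


def classify_pairs_bound(pairs: pd.DataFrame, matches: IntervalSet,
                         peaks: IntervalSet) -> pd.Series:
    """Pair bound status against a peak set: True if both members overlap a
    peak, False if neither does, NA (excluded) for mixed pairs."""
    member_bound = matches._overlap_mask(peaks)
    a = member_bound[pairs["idx_a"].to_numpy()]
    b = member_bound[pairs["idx_b"].to_numpy()]
    out = pd.Series(pd.NA, index=pairs.index, dtype="boolean")
    out[a & b] = True
    out[~a & ~b] = False
    return out


def distance_enrichment(pairs: pd.DataFrame, bound: pd.Series,
                        alpha: float = 0.05,
                        report_band: tuple[int, int] = REPORT_BAND):
    """Hypergeometric enrichment of each pair distance in the bound fraction.

    Population: all classified pairs (N); successes: pairs at distance d
    (m); draws: bound pairs (n); observed: bound pairs at d (q). The
    upper-tail p-value P[X >= q] is computed per distance and flagged
    significant at ``alpha``. Also reports the aggregate fraction of bound
    and unbound pairs falling in the 12-50 bp band.
    """
    keep = bound.notna()
    pairs = pairs[keep.to_numpy()]
    flags = bound[keep].astype(bool).to_numpy()
    N = len(pairs)
    n_bound = int(flags.sum())
    if n_bound == 0 or n_bound == N:
        raise ValueError("need both bound and unbound pairs")
    dist = pairs["distance"].to_numpy()
    rows = []
    for d in np.unique(dist):
        at_d = dist == d
        m = int(at_d.sum())
        q = int((at_d & flags).sum())
        p = float(stats.hypergeom.sf(q - 1, N, m, n_bound))
        rows.append((int(d), m, q, p, p < alpha))
    table = pd.DataFrame(
        rows, columns=["distance", "all_at_d", "bound_at_d", "p", "significant"]
    )
    lo, hi = report_band
    in_band = (dist >= lo) & (dist <= hi)
    summary = {
        "n_pairs": N,
        "n_bound": n_bound,
        "bound_frac_in_band": float(in_band[flags].mean()) if n_bound else 0.0,
        "unbound_frac_in_band": float(in_band[~flags].mean()),
    }
    return table, summary
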