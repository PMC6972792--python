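"""Stand-in enrichment peak caller.

This module reproduces the *semantics* the downstream analysis depends on —
fixed-size "factor" peaks vs stitched variable-length "region" peaks, a
stringent gate (FDR <= 1e-5 and >= 15 normalized tags), and replicate-aware
differential regions — with explicitly stated Poisson / Benjamini–Hochberg
statistics. It is intentionally NOT a bit-level reimplementation of any
published caller.

Candidate windows are evaluated on a stride of half the window size;
overlapping candidates are resolved greedily, keeping the higher count
(ties go to the leftmost window). Window significance is a Poisson
upper-tail test of the observed count against max(local control rate,
genome-wide rate), BH-corrected across candidate windows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import IntervalSet
from .tracks import SignalTrack

STRINGENT_FDR = 1e-5
STRINGENT_MIN_NORM_TAGS = 15.0


def normalize_counts(raw, library_size: float):
    """Convert raw tag counts to tags per 10^7 sequenced reads."""
    if library_size <= 0:
        raise ValueError("library size must be positive")
    return np.asarray(raw, dtype=float) * 1e7 / library_size


def _candidate_windows(tags: SignalTrack, control: SignalTrack | None,
                       size: int, local_factor: int = 10):
    """Greedy non-overlapping windows with Poisson p-values, per chromosome."""
    if size <= 0:
        raise ValueError("window size must be positive")
    genome_len = sum(tags.chrom_sizes.values())
    genome_rate = tags.total / genome_len  # tags per base
    lib_ratio = 1.0
    if control is not None:
        ctrl_total = control.library_size or control.total
        if ctrl_total > 0:
            lib_ratio = (tags.library_size or tags.total) / ctrl_total
    rows = []
    step = max(size // 2, 1)
    for chrom, arr in tags.data.items():
        n = len(arr)
        if n < size:
            continue
        starts = np.arange(0, n - size + 1, step)
        counts = tags.interval_sums(chrom, starts, starts + size)
        cand = counts > 0
        starts, counts = starts[cand], counts[cand]
        if not len(starts):
            continue
        # greedy: highest count first, leftmost on ties
        order = np.lexsort((starts, -counts))
        occupied = np.zeros(n, dtype=bool)
        kept = []
        for i in order:
            s = int(starts[i])
            if occupied[s : s + size].any():
                continue
            occupied[s : s + size] = True
            kept.append(i)
        kept = np.array(sorted(kept, key=lambda i: starts[i]))
        ks, kc = starts[kept], counts[kept]
        # expected counts under the background model
        lam = np.full(len(ks), genome_rate * size)
        if control is not None:
            span = size * local_factor
            centers = ks + size // 2
            local = control.interval_sums(
                chrom, centers - span // 2, centers + span // 2
            )
            local_rate = local / span * lib_ratio * size
            same_window = control.interval_sums(chrom, ks, ks + size) * lib_ratio
            lam = np.maximum(lam, np.maximum(local_rate, same_window))
        pvals = stats.poisson.sf(kc - 1, lam)
        for s, c, l, p in zip(ks, kc, lam, pvals):
            rows.append((chrom, int(s), int(s) + size, float(c), float(l), float(p)))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "count", "expected", "p"]
    )


def call_peaks_factor(tags: SignalTrack, control: SignalTrack | None = None,
                      size: int = 200, fdr: float = 0.05,
                      stringent: bool = False) -> IntervalSet:
    """Fixed-size factor-mode peaks.

    ``stringent`` additionally enforces FDR <= 1e-5 and a minimal normalized
    tag count of 15 tags per peak.
    """
    if stringent:
        fdr = min(fdr, STRINGENT_FDR)
    cand = _candidate_windows(tags, control, size)
    if not len(cand):
        return IntervalSet.empty(["norm_count", "p", "q", "summit", "mode"])
    _, q, _, _ = multipletests(cand["p"], alpha=fdr, method="fdr_bh")[:4]
    cand = cand.assign(q=q)
    cand = cand[cand["q"] <= fdr]
    lib = tags.library_size or tags.total
    cand = cand.assign(norm_count=normalize_counts(cand["count"], lib), mode="factor")
    if stringent:
        cand = cand[cand["norm_count"] >= STRINGENT_MIN_NORM_TAGS]
    summits = []
    for row in cand.itertuples(index=False):
        arr = tags[row.chrom][row.start : row.end]
        summits.append(row.start + int(np.argmax(arr)))
    cand = cand.assign(summit=summits)
    cols = ["chrom", "start", "end", "norm_count", "p", "q", "summit", "mode"]
    return IntervalSet(cand[cols].reset_index(drop=True), validate=False).sort()


def call_peaks_region(tags: SignalTrack, control: SignalTrack | None = None,
                      size: int = 150, min_dist: int = 250, fdr: float = 1e-5,
                      min_fold: float = 2.0) -> IntervalSet:
    """Variable-length region-mode peaks: significant nucleosome-size windows
    with local enrichment >= ``min_fold`` are stitched when their centers are
    closer than ``min_dist``."""
    cand = _candidate_windows(tags, control, size)
    if not len(cand):
        return IntervalSet.empty()
    _, q, _, _ = multipletests(cand["p"], alpha=fdr, method="fdr_bh")[:4]
    called = cand[(q <= fdr) & (cand["count"] >= min_fold * cand["expected"])]
    if not len(called):
        return IntervalSet.empty()
    # stitch windows whose centers are closer than min_dist
    gap = max(min_dist - size, 0)
    return IntervalSet(called[["chrom", "start", "end"]], validate=False).merge(
        gap if gap > 0 else 0
    )


def differential_regions(a_reps: list[SignalTrack], b_reps: list[SignalTrack],
                         regions: IntervalSet, min_fold: float = 2.0,
                         alpha: float = 0.05) -> pd.DataFrame:
    """Classify regions as up / down / unchanged in condition *b* vs *a*.

    Per region, replicate counts are summed per condition and compared with
    the exact conditional binomial form of a two-sided Poisson rate test,
    with the summed library sizes as exposures; BH correction across
    regions. A region is called only if the normalized fold change also
    passes ``min_fold`` (conjunctive gates).
    """
    if not a_reps or not b_reps:
        raise ValueError("need >= 1 replicate per condition")
    if not len(regions):
        return pd.DataFrame(
            columns=["chrom", "start", "end", "mean_a", "mean_b", "fold_b_vs_a",
                     "p", "q", "status"]
        )
    lib_a = sum(t.library_size or t.total for t in a_reps)
    lib_b = sum(t.library_size or t.total for t in b_reps)
    sum_a = np.zeros(len(regions))
    sum_b = np.zeros(len(regions))
    for t in a_reps:
        sum_a += t.set_sums(regions)
    for t in b_reps:
        sum_b += t.set_sums(regions)
    mean_a = sum_a / len(a_reps) * 1e7 / (lib_a / len(a_reps))
    mean_b = sum_b / len(b_reps) * 1e7 / (lib_b / len(b_reps))
    expect_b = lib_b / (lib_a + lib_b)
    pvals = np.ones(len(regions))
    for i, (ca, cb) in enumerate(zip(sum_a, sum_b)):
        ka, kb = int(round(ca)), int(round(cb))
        if ka + kb > 0:
            pvals[i] = stats.binomtest(kb, ka + kb, expect_b).pvalue
    _, qvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")[:4]
    rate_a = sum_a / lib_a
    rate_b = sum_b / lib_b
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(rate_a > 0, rate_b / rate_a, np.inf)
        fold = np.where((rate_a == 0) & (rate_b == 0), 1.0, fold)
    status = np.full(len(regions), "unchanged", dtype=object)
    sig = qvals <= alpha
    status[sig & (fold >= min_fold)] = "up"
    status[sig & (fold <= 1.0 / min_fold)] = "down"
    out = regions.df[["chrom", "start", "end"]].copy()
    out["mean_a"] = mean_a
    out["mean_b"] = mean_b
    out["fold_b_vs_a"] = fold
    out["p"] = pvals
    out["q"] = qvals
    out["status"] = status
    return out
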