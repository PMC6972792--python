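"""Bound-vs-unbound motif prediction.

Assembles a per-motif feature table (motif log-odds score, mean
conservation, binary co-motif presence within 6-100 bp of the motif center,
and pre/post-induction accessibility in 50-bp motif-centered windows,
labeled by overlap with a stringent peak), fits ridge-stabilized logistic
models over nested predictor sets on a random half of the candidate sites,
and compares them by ROC curves and AUC on the held-out half.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .intervals import IntervalSet
from .tracks import SignalTrack

CO_MOTIF_BAND = (6, 100)  # bp from motif center
ACC_WINDOW = 50
RIDGE = 1e-6

def predictor_sets(feature_columns: list[str]) -> dict[str, list[str]]:
    """The three nested default predictor sets, resolved against a table."""
    co = [c for c in feature_columns if c.startswith("co_")]
    seq = ["score", "conservation"] + co
    return {
        "sequence": seq,
        "sequence+preATAC": seq + ["acc_pre"],
        "sequence+pre+postATAC": seq + ["acc_pre", "acc_post"],
    }


def assemble_features(matches: IntervalSet, conservation: SignalTrack,
                      class_matches: dict[str, IntervalSet],
                      atac_pre: SignalTrack, atac_post: SignalTrack,
                      stringent_peaks: IntervalSet,
                      acc_window: int = ACC_WINDOW,
                      co_band: tuple[int, int] = CO_MOTIF_BAND) -> pd.DataFrame:
    """One feature row per (mappability-filtered) motif match."""
    df = matches.df
    n = len(df)
    centers = matches.centers()
    chroms = df["chrom"].to_numpy()
    out = pd.DataFrame(index=range(n))
    out["score"] = df["score"].to_numpy() if "score" in df.columns else 0.0
    cons = np.zeros(n)
    acc = {"acc_pre": np.zeros(n), "acc_post": np.zeros(n)}
    for chrom in np.unique(chroms):
        sel = chroms == chrom
        s = df.loc[sel, "start"].to_numpy()
        e = df.loc[sel, "end"].to_numpy()
        cons[sel] = conservation.interval_sums(chrom, s, e) / (e - s)
        for key, track in (("acc_pre", atac_pre), ("acc_post", atac_post)):
            acc[key][sel] = (
                track.window_sums(chrom, centers[sel], acc_window) * track.norm_scale
            )
    out["conservation"] = cons
    lo, hi = co_band
    for name in sorted(class_matches):
        m = class_matches[name]
        mc = (m.df["start"].to_numpy() + m.df["end"].to_numpy()) // 2
        mchrom = m.df["chrom"].to_numpy()
        flag = np.zeros(n, dtype=bool)
        for chrom in np.unique(chroms):
            sel = chroms == chrom
            cpos = np.sort(mc[mchrom == chrom])
            if not len(cpos):
                continue
            c = centers[sel]
            # any class-motif center with |distance| in [lo, hi]
            left = np.searchsorted(cpos, c - hi)
            right = np.searchsorted(cpos, c + hi, side="right")
            near_l = np.searchsorted(cpos, c - lo + 1)
            near_r = np.searchsorted(cpos, c + lo - 1, side="right")
            flag[sel] = (right - left) - np.maximum(near_r - near_l, 0) > 0
        out[f"co_{name}"] = flag.astype(float)
    out["acc_pre"] = acc["acc_pre"]
    out["acc_post"] = acc["acc_post"]
    out["bound"] = matches._overlap_mask(stringent_peaks).astype(int)
    if not np.all(np.isfinite(out.select_dtypes(float).to_numpy())):
        raise ValueError("non-finite feature values")
    return out


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class LogisticModel:
    predictor_set: str
    features: list[str]
    coef: np.ndarray  # intercept first
    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int
    n_iter: int

    def decision(self, table: pd.DataFrame) -> np.ndarray:
        X = table[self.features].to_numpy(dtype=float)
        return self.coef[0] + X @ self.coef[1:]

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        return _sigmoid(self.decision(table))


def split_half(n: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Random exact half split (train, test), seeded, unstratified."""
    perm = np.random.default_rng(seed).permutation(n)
    half = n // 2
    return np.sort(perm[:half]), np.sort(perm[half:])


def fit_logistic(table: pd.DataFrame, features: list[str], split_seed: int = 0,
                 name: str = "model", ridge: float = RIDGE,
                 train_idx: np.ndarray | None = None,
                 test_idx: np.ndarray | None = None,
                 max_iter: int = 100, tol: float = 1e-8) -> LogisticModel:
    """Ridge-stabilized logistic regression by IRLS on a random half.

    Maximizes the Bernoulli log-likelihood minus ``ridge/2 * ||beta||^2``
    (intercept unpenalized) to a gradient max-norm of ``tol``; the tiny
    ridge keeps separable training halves finite.
    """
    if train_idx is None or test_idx is None:
        train_idx, test_idx = split_half(len(table), split_seed)
    y = table["bound"].to_numpy(dtype=float)[train_idx]
    if y.min() == y.max():
        raise ValueError("training half contains a single class")
    X = np.column_stack(
        [np.ones(len(train_idx)), table[features].to_numpy(dtype=float)[train_idx]]
    )
    beta = np.zeros(X.shape[1])
    penalty = np.full(X.shape[1], ridge)
    penalty[0] = 0.0
    for it in range(1, max_iter + 1):
        p = _sigmoid(X @ beta)
        grad = X.T @ (y - p) - penalty * beta
        if np.max(np.abs(grad)) <= tol:
            break
        w = np.clip(p * (1.0 - p), 1e-12, None)
        H = (X * w[:, None]).T @ X + np.diag(penalty)
        beta = beta + np.linalg.solve(H, grad)
    else:
        raise RuntimeError(
            f"IRLS did not converge in {max_iter} iterations "
            f"(|grad|={np.max(np.abs(grad)):.3g})"
        )
    return LogisticModel(
        predictor_set=name, features=list(features), coef=beta,
        train_idx=train_idx, test_idx=test_idx, seed=split_seed, n_iter=it,
    )


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_auc(model: LogisticModel, table: pd.DataFrame) -> RocResult:
    """ROC curve and AUC on the model's held-out half.

    The AUC equals the probability that a random positive outscores a random
    negative, ties counting one half (trapezoidal integration of the
    threshold-swept curve).
    """
    y = table["bound"].to_numpy(dtype=int)[model.test_idx]
    if y.min() == y.max():
        raise ValueError("evaluation half contains a single class")
    scores = model.decision(table.iloc[model.test_idx])
    fpr, tpr, thr = roc_curve(y, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc)


def compare_predictor_sets(table: pd.DataFrame,
                           sets: dict[str, list[str]] | None = None,
                           split_seed: int = 0) -> pd.DataFrame:
    """Fit every predictor set on one shared train/test split and report AUCs."""
    if sets is None:
        sets = predictor_sets(list(table.columns))
    if len(sets) < 2:
        raise ValueError("need >= 2 predictor sets to compare")
    train_idx, test_idx = split_half(len(table), split_seed)
    rows = []
    for name, feats in sets.items():
        model = fit_logistic(table, feats, split_seed, name=name,
                             train_idx=train_idx, test_idx=test_idx)
        rows.append((name, roc_auc(model, table).auc, len(feats), split_seed))
    return pd.DataFrame(rows, columns=["predictor_set", "auc", "n_features", "seed"])


def mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Exact pairwise-concordance AUC (ties count 1/2); testing oracle and
    invariant check for :func:`roc_auc`."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return float(wins / (len(pos) * len(neg)))
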