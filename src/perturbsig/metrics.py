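"""Evaluation metrics for inferred differential-expression signatures.

RMSE and Pearson correlation measure agreement over all landmark genes;
Positive/Negative Precision@K focus on the most strongly up-/down-regulated
genes (K = 100 by convention for 978-gene signatures).  SSE, MSE, MAE and a
"multiple r^2" (squared Pearson correlation; the usual goodness-of-fit
reading) are reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr


@dataclass
class MetricReport:
    rmse: float
    pearson: float
    precision_pos_at_k: float
    precision_neg_at_k: float
    sse: float
    mse: float
    mae: float
    r2: float
    k: int
    n: int


def _check(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"vectors must be 1-D of equal length, got "
                         f"{a.shape} vs {b.shape}")
    return a, b


def rmse(true_dx, pred_dx) -> float:
    """Root mean squared error."""
    a, b = _check(true_dx, pred_dx)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def pearson(a, b, nan_on_constant: bool = False) -> float:
    """Pearson correlation; constant input raises unless flagged to NaN."""
    a, b = _check(a, b)
    if np.std(a) == 0 or np.std(b) == 0:
        if nan_on_constant:
            return float("nan")
        raise ValueError("pearson undefined for zero-variance input")
    return float(pearsonr(a, b).statistic)


def _topk_idx(v: np.ndarray, k: int, direction: str) -> np.ndarray:
    """Indices of the k largest (positive) or smallest (negative) entries,
    ties broken by ascending gene index."""
    if direction == "positive":
        order = np.argsort(-v, kind="stable")
    elif direction == "negative":
        order = np.argsort(v, kind="stable")
    else:
        raise ValueError(f"direction must be positive/negative, "
                         f"got {direction!r}")
    return order[:k]


def precision_at_k(true_dx, pred_dx, k: int = 100,
                   direction: str = "positive") -> float:
    """Overlap fraction of true and predicted top-k gene sets.

    ``positive`` compares the k most up-regulated genes, ``negative`` the k
    most down-regulated.
    """
    a, b = _check(true_dx, pred_dx)
    if k > a.shape[0]:
        raise ValueError(f"k={k} exceeds gene count {a.shape[0]}")
    top_true = set(_topk_idx(a, k, direction).tolist())
    top_pred = set(_topk_idx(b, k, direction).tolist())
    return len(top_true & top_pred) / k


def metric_report(true_dx, pred_dx, k: int = 100) -> MetricReport:
    """All eight metrics for one signature pair."""
    a, b = _check(true_dx, pred_dx)
    err = a - b
    sse = float(np.sum(err ** 2))
    mse = sse / a.shape[0]
    r = pearson(a, b, nan_on_constant=True)
    return MetricReport(
        rmse=float(np.sqrt(mse)),
        pearson=r,
        precision_pos_at_k=precision_at_k(a, b, k, "positive"),
        precision_neg_at_k=precision_at_k(a, b, k, "negative"),
        sse=sse,
        mse=mse,
        mae=float(np.mean(np.abs(err))),
        r2=r * r,
        k=k,
        n=a.shape[0],
    )


def metric_report_batch(true_mat, pred_mat, k: int = 100) -> MetricReport:
    """Per-sample metrics averaged over a dataset (rows = samples)."""
    true_mat = np.atleast_2d(np.asarray(true_mat, dtype=float))
    pred_mat = np.atleast_2d(np.asarray(pred_mat, dtype=float))
    if true_mat.shape != pred_mat.shape:
        raise ValueError("matrix shapes differ")
    reports = [metric_report(t, p, k) for t, p in zip(true_mat, pred_mat)]
    mean = lambda f: float(np.nanmean([getattr(r, f) for r in reports]))
    return MetricReport(
        rmse=mean("rmse"), pearson=mean("pearson"),
        precision_pos_at_k=mean("precision_pos_at_k"),
        precision_neg_at_k=mean("precision_neg_at_k"),
        sse=mean("sse"), mse=mean("mse"), mae=mean("mae"), r2=mean("r2"),
        k=k, n=true_mat.shape[1],
    )
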