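"""Covariate balance diagnostics.

Standardized mean differences (SMD) and weighted Kolmogorov-Smirnov
statistics between treatment arms, before and after propensity
weighting, assessed against a 0.20 threshold.

SMD is reported unsigned: |m_a - m_b| / sqrt((v_a + v_b) / 2), with
weighted means and population-style (sum-of-weights denominator)
weighted variances; binary covariates use the Bernoulli variance
p(1 - p).  The KS statistic is the supremum over observed values of the
absolute difference of the two weighted empirical CDFs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "smd",
    "smd_from_prevalence",
    "ks_statistic",
    "balance_table",
    "weighted_mean",
    "weighted_var",
    "BALANCE_THRESHOLD",
]

BALANCE_THRESHOLD = 0.20


def weighted_mean(x, w=None) -> float:
    # unit weights share the weighted code path so that the unweighted
    # and weighted results are bit-identical
    x = np.asarray(x, dtype=float)
    w = np.ones_like(x) if w is None else np.asarray(w, dtype=float)
    return float(np.sum(w * x) / np.sum(w))


def weighted_var(x, w=None) -> float:
    """Population-style weighted variance (sum-of-weights denominator)."""
    x = np.asarray(x, dtype=float)
    w = np.ones_like(x) if w is None else np.asarray(w, dtype=float)
    m = weighted_mean(x, w)
    return float(np.sum(w * (x - m) ** 2) / np.sum(w))


def smd(
    values_a,
    values_b,
    weights_a=None,
    weights_b=None,
    kind: str = "continuous",
) -> float:
    """Absolute standardized mean difference between two groups.

    ``kind="binary"`` uses the Bernoulli variance p(1-p) per group.
    Zero pooled variance with unequal means yields ``inf``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    ma, mb = weighted_mean(a, weights_a), weighted_mean(b, weights_b)
    if kind == "binary":
        va, vb = ma * (1.0 - ma), mb * (1.0 - mb)
    elif kind == "continuous":
        va, vb = weighted_var(a, weights_a), weighted_var(b, weights_b)
    else:
        raise ValueError(f"unknown kind {kind!r}")
    pooled = (va + vb) / 2.0
    diff = abs(ma - mb)
    if pooled <= 0.0:
        return 0.0 if diff == 0.0 else float("inf")
    return diff / float(np.sqrt(pooled))


def smd_from_prevalence(p_a: float, p_b: float) -> float:
    """Binary-covariate SMD directly from two group prevalences."""
    pooled = (p_a * (1 - p_a) + p_b * (1 - p_b)) / 2.0
    diff = abs(p_a - p_b)
    if pooled <= 0.0:
        return 0.0 if diff == 0.0 else float("inf")
    return diff / float(np.sqrt(pooled))


def ks_statistic(values_a, values_b, weights_a=None, weights_b=None) -> float:
    """Weighted two-sample KS statistic: sup |ECDF_a - ECDF_b|."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    wa = np.ones_like(a) if weights_a is None else np.asarray(weights_a, dtype=float)
    wb = np.ones_like(b) if weights_b is None else np.asarray(weights_b, dtype=float)
    grid = np.unique(np.concatenate([a, b]))

    def ecdf(x, w):
        order = np.argsort(x, kind="mergesort")
        xs, ws = x[order], w[order]
        cum = np.cumsum(ws) / np.sum(ws)
        idx = np.searchsorted(xs, grid, side="right")
        return np.where(idx > 0, cum[np.minimum(idx - 1, len(cum) - 1)], 0.0)

    return float(np.max(np.abs(ecdf(a, wa) - ecdf(b, wb))))


@dataclass
class BalanceReport:
    """Balance of every covariate in one moderator level, pre/post weighting."""

    table: pd.DataFrame  # index: covariate; columns: smd_unweighted, ...
    threshold: float
    moderator_level: int | None = None

    @property
    def all_pass(self) -> bool:
        return bool(self.table["balanced"].all())

    def failing(self) -> list[str]:
        return list(self.table.index[~self.table["balanced"]])


def _infer_kind(x: np.ndarray) -> str:
    vals = np.unique(x[~np.isnan(x)])
    return "binary" if np.isin(vals, (0.0, 1.0)).all() else "continuous"


def balance_table(
    frame: pd.DataFrame,
    treatment: str,
    covariates,
    weights=None,
    threshold: float = BALANCE_THRESHOLD,
    moderator_level: int | None = None,
) -> BalanceReport:
    """Evaluate SMD and KS for each covariate, unweighted and weighted.

    A covariate passes when both its weighted SMD and weighted KS fall
    strictly below the threshold.  With ``weights=None`` the weighted
    columns equal the unweighted ones (all weights 1).
    """
    t = np.asarray(frame[treatment], dtype=float)
    if not ((t == 0) | (t == 1)).all():
        raise ValueError("treatment must be binary 0/1")
    w = np.ones(len(frame)) if weights is None else np.asarray(weights, dtype=float)
    rows = {}
    for cov in covariates:
        x = np.asarray(frame[cov], dtype=float)
        a, b = x[t == 1], x[t == 0]
        wa, wb = w[t == 1], w[t == 0]
        kind = _infer_kind(x)
        s_u = smd(a, b, kind=kind)
        s_w = smd(a, b, wa, wb, kind=kind)
        k_u = ks_statistic(a, b)
        k_w = ks_statistic(a, b, wa, wb)
        rows[cov] = {
            "kind": kind,
            "smd_unweighted": s_u,
            "smd_weighted": s_w,
            "ks_unweighted": k_u,
            "ks_weighted": k_w,
            "balanced": (s_w < threshold) and (k_w < threshold),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    return BalanceReport(table=table, threshold=threshold, moderator_level=moderator_level)
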