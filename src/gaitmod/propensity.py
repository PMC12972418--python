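"""Propensity-score estimation and inverse-probability ATE weights.

Propensity scores for treatment (statin use) are estimated separately
within each moderator level.  The default estimator is stagewise
gradient-boosted logistic modelling with shallow trees, with the number
of boosting iterations chosen to optimize a covariate-balance criterion
(mean or max weighted SMD, or mean weighted KS) — the strategy of
balance-tuned boosting for propensity weighting.  A penalized logistic
model is available as a fast, always-converging alternative.

Missing covariate values are not dropped: numeric missings are imputed
with a constant outside the observed range and a per-covariate
missingness indicator joins the covariate set, so the weights also
balance missingness rates between arms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression

from .balance import ks_statistic, smd

__all__ = [
    "PSModelConfig",
    "OverlapReport",
    "WeightedCohort",
    "screen_overlap",
    "prepare_covariates",
    "fit_propensity",
    "ate_weights",
    "PS_CLIP",
]

PS_CLIP = 1e-4  # probabilities clipped into [PS_CLIP, 1 - PS_CLIP]


@dataclass
class PSModelConfig:
    """Configuration of the propensity model.

    method: "gbm" (balance-tuned boosting) or "logistic" (penalized
    logistic; fast fallback).  ``stop_criterion`` selects the balance
    summary minimized over boosting iterations.
    """

    method: str = "gbm"
    max_trees: int = 300
    shrinkage: float = 0.05
    interaction_depth: int = 3
    stop_criterion: str = "mean-smd"  # mean-smd | max-smd | mean-ks
    eval_every: int = 10
    weight_truncate: Optional[float] = 0.99  # within-arm quantile cap on raw weights
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.shrinkage <= 1.0:
            raise ValueError("shrinkage must be in (0, 1]")
        if self.max_trees < 1:
            raise ValueError("max_trees must be >= 1")
        if self.stop_criterion not in {"mean-smd", "max-smd", "mean-ks"}:
            raise ValueError(f"unknown stop criterion {self.stop_criterion!r}")
        if self.method not in {"gbm", "logistic"}:
            raise ValueError(f"unknown method {self.method!r}")


@dataclass
class OverlapReport:
    """Covariate-overlap screen across the 4 treatment x moderator cells."""

    excluded_levels: list[tuple[str, float, int]] = field(default_factory=list)
    flagged_numeric: list[str] = field(default_factory=list)
    analyzable: bool = True
    n_before: int = 0
    n_after: int = 0


@dataclass
class WeightedCohort:
    """One moderator level with per-row propensities and ATE weights."""

    frame: pd.DataFrame
    propensity: np.ndarray
    weight: np.ndarray
    moderator_level: int
    treatment: str
    diagnostics: dict = field(default_factory=dict)


def _is_binary(x: np.ndarray) -> bool:
    vals = np.unique(x[~np.isnan(x)])
    return vals.size <= 2 and np.isin(vals, (0.0, 1.0)).all()


def screen_overlap(
    frame: pd.DataFrame,
    treatment: str,
    moderator: str,
    covariates: Sequence[str],
) -> tuple[OverlapReport, pd.DataFrame]:
    """Flag covariate subgroups with substantial non-overlap and trim them.

    A binary/categorical covariate level is excluded when any of the four
    treatment x moderator cells contains no member of that level (e.g.,
    no treated moderator-positive females): rows at that level are
    dropped and listed.  Numeric covariates are flagged, not trimmed,
    when any two cells have disjoint interquartile ranges.  If a cell
    ends up empty the moderator is marked non-analyzable.
    """
    report = OverlapReport(n_before=len(frame))
    t = np.asarray(frame[treatment], dtype=float)
    m = np.asarray(frame[moderator], dtype=float)
    cells = [(ti, mi) for ti in (0, 1) for mi in (0, 1)]
    masks = {c: (t == c[0]) & (m == c[1]) for c in cells}
    if any(not msk.any() for msk in masks.values()):
        report.analyzable = False
        report.n_after = len(frame)
        return report, frame

    keep = np.ones(len(frame), dtype=bool)
    for cov in covariates:
        x = np.asarray(frame[cov], dtype=float)
        if _is_binary(x):
            for level in np.unique(x[~np.isnan(x)]):
                if any((x[msk] == level).sum() == 0 for msk in masks.values()):
                    drop = x == level
                    report.excluded_levels.append((cov, float(level), int(drop.sum())))
                    keep &= ~drop
        else:
            iqrs = {}
            for c, msk in masks.items():
                vals = x[msk]
                vals = vals[~np.isnan(vals)]
                if vals.size:
                    iqrs[c] = (np.percentile(vals, 25), np.percentile(vals, 75))
            pairs = list(iqrs.values())
            disjoint = any(
                lo1 > hi2 or lo2 > hi1
                for i, (lo1, hi1) in enumerate(pairs)
                for (lo2, hi2) in pairs[i + 1 :]
            )
            if disjoint:
                report.flagged_numeric.append(cov)

    trimmed = frame.loc[keep]
    report.n_after = len(trimmed)
    tt = np.asarray(trimmed[treatment], dtype=float)
    mm = np.asarray(trimmed[moderator], dtype=float)
    if any(((tt == c[0]) & (mm == c[1])).sum() == 0 for c in cells):
        report.analyzable = False
    return report, trimmed


def prepare_covariates(
    frame: pd.DataFrame, covariates: Sequence[str]
) -> tuple[pd.DataFrame, list[str]]:
    """Impute missings out-of-range and append missingness indicators.

    Returns the design frame and the full covariate list (original
    columns plus one ``<cov>_missing`` indicator per covariate that had
    any missing values), so downstream balance checks cover missingness.
    """
    out = {}
    names: list[str] = []
    for cov in covariates:
        x = pd.to_numeric(frame[cov], errors="coerce").astype(float)
        miss = x.isna()
        if miss.any():
            observed = x.dropna()
            if observed.empty:
                fill = 0.0
            else:
                rng_span = float(observed.max() - observed.min())
                fill = float(observed.max() + max(rng_span, 1.0) + 1.0)
            x = x.fillna(fill)
            out[f"{cov}_missing"] = miss.astype(float)
            names.append(cov)
            names.append(f"{cov}_missing")
        else:
            names.append(cov)
        out[cov] = x
    design = pd.DataFrame(out, index=frame.index)
    return design[names], names


def _balance_criterion(
    X: pd.DataFrame, t: np.ndarray, ps: np.ndarray, criterion: str
) -> float:
    w = ate_weights(ps, t, stabilize=False)
    stats = []
    for cov in X.columns:
        x = np.asarray(X[cov], dtype=float)
        kind = "binary" if _is_binary(x) else "continuous"
        if criterion == "mean-ks":
            stats.append(ks_statistic(x[t == 1], x[t == 0], w[t == 1], w[t == 0]))
        else:
            s = smd(x[t == 1], x[t == 0], w[t == 1], w[t == 0], kind=kind)
            stats.append(s if np.isfinite(s) else 10.0)
    if criterion == "max-smd":
        return float(np.max(stats))
    return float(np.mean(stats))


def fit_propensity(
    frame: pd.DataFrame,
    treatment: str,
    covariates: Sequence[str],
    config: Optional[PSModelConfig] = None,
) -> tuple[np.ndarray, dict]:
    """Estimate per-row treatment propensities within one moderator level.

    Returns probabilities clipped into (0, 1) and a diagnostics dict
    (chosen iteration, balance criterion value, clipping count,
    expanded covariate list).
    """
    config = config or PSModelConfig()
    t = np.asarray(frame[treatment], dtype=float)
    classes = np.unique(t)
    if classes.size < 2:
        raise ValueError("treatment has a single class; propensity model is undefined")
    X, names = prepare_covariates(frame, covariates)
    Xv = X.to_numpy(dtype=float)

    diagnostics: dict = {"covariates": names, "method": config.method}
    if config.method == "gbm":
        model = GradientBoostingClassifier(
            n_estimators=config.max_trees,
            learning_rate=config.shrinkage,
            max_depth=config.interaction_depth,
            random_state=config.seed,
        )
        try:
            model.fit(Xv, t)
            best_ps, best_crit, best_iter = None, np.inf, 0
            for i, proba in enumerate(model.staged_predict_proba(Xv), start=1):
                if i % config.eval_every and i != config.max_trees:
                    continue
                ps = np.clip(proba[:, 1], PS_CLIP, 1 - PS_CLIP)
                crit = _balance_criterion(X, t, ps, config.stop_criterion)
                if crit < best_crit:
                    best_ps, best_crit, best_iter = ps, crit, i
            assert best_ps is not None
            diagnostics.update(n_trees=best_iter, criterion=best_crit)
            ps = best_ps
        except Exception as exc:  # non-convergence: fall back, keep going
            warnings.warn(f"boosted propensity fit failed ({exc}); using logistic fallback")
            ps = _logistic_ps(Xv, t, config.seed)
            diagnostics.update(method="logistic-fallback")
    else:
        ps = _logistic_ps(Xv, t, config.seed)
        diagnostics["criterion"] = _balance_criterion(X, t, ps, config.stop_criterion)

    n_clipped = int(np.sum((ps <= PS_CLIP) | (ps >= 1 - PS_CLIP)))
    diagnostics["n_clipped"] = n_clipped
    return ps, diagnostics


def _logistic_ps(Xv: np.ndarray, t: np.ndarray, seed: int) -> np.ndarray:
    # near-MLE: the tiny ridge penalty only guards against separation;
    # stronger shrinkage was found to leave residual confounder imbalance
    # in small moderator-level subsets
    mu = Xv.mean(axis=0)
    sd = Xv.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (Xv - mu) / sd
    model = LogisticRegression(C=1e4, max_iter=5000, random_state=seed)
    model.fit(Z, t)
    return np.clip(model.predict_proba(Z)[:, 1], PS_CLIP, 1 - PS_CLIP)


def ate_weights(
    propensity,
    treatment,
    stabilize: bool = True,
    truncate_quantile: Optional[float] = None,
) -> np.ndarray:
    """Inverse-probability ATE weights: treated 1/ps, control 1/(1-ps).

    With ``stabilize=True`` weights are normalized to mean 1 within each
    arm; this rescaling leaves weighted mean differences unchanged.
    ``truncate_quantile`` caps raw weights at that within-arm quantile
    (e.g. 0.99), the usual guard against a handful of extreme weights
    dominating the weighted moments.
    """
    ps = np.asarray(propensity, dtype=float)
    t = np.asarray(treatment, dtype=float)
    if np.any((ps <= 0) | (ps >= 1)):
        raise ValueError("propensity must lie strictly inside (0, 1)")
    w = np.where(t == 1, 1.0 / ps, 1.0 / (1.0 - ps))
    if truncate_quantile is not None:
        if not 0.5 < truncate_quantile <= 1.0:
            raise ValueError("truncate_quantile must be in (0.5, 1]")
        for arm in (0, 1):
            mask = t == arm
            if mask.any():
                cap = np.quantile(w[mask], truncate_quantile)
                w[mask] = np.minimum(w[mask], cap)
    if stabilize:
        for arm in (0, 1):
            mask = t == arm
            if mask.any():
                w[mask] = w[mask] / w[mask].mean()
    return w
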