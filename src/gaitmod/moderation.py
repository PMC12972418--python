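"""Moderated treatment-effect estimation.

Fits the PS-weighted interaction model

    Y = b0 + (b1 + b3*M) * X + b2*M (+ adjustment covariates)

by weighted least squares with heteroskedasticity-robust (HC1) standard
errors, where X is the binary treatment (statin use), M a binary
moderator (a concomitant drug class) and Y a continuous gait outcome in
cm/s.  The moderated average treatment effects follow from the fitted
coefficients: M-ATE0 = b1 and M-ATE1 = b1 + b3, so the interaction
coefficient equals M-ATE1 - M-ATE0 identically.

``run_all_moderators`` orchestrates the full five-step procedure per
candidate moderator: overlap screen, per-moderator-level propensity
fit (all concomitant drug classes except the moderator itself enter as
covariates), balance diagnostics at the 0.20 threshold, the weighted
interaction fit, and tabulation.  No multiple-testing correction is
applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .balance import BALANCE_THRESHOLD, BalanceReport, balance_table, weighted_mean
from .propensity import (
    OverlapReport,
    PSModelConfig,
    ate_weights,
    fit_propensity,
    prepare_covariates,
    screen_overlap,
)

__all__ = [
    "ModerationResult",
    "fit_weighted_interaction",
    "average_marginal_effect",
    "weighted_mean_difference",
    "run_single_moderator",
    "run_all_moderators",
    "run_stratified",
]


@dataclass
class Estimate:
    value: float
    ci_low: float
    ci_high: float
    p_value: Optional[float] = None


@dataclass
class ModerationResult:
    """Coefficients and moderated treatment effects for one moderator."""

    moderator: str
    outcome: str
    beta0: Estimate
    beta1: Estimate
    beta2: Estimate
    beta3: Estimate
    m_ate_0: Estimate
    m_ate_1: Estimate
    ame_0: float
    ame_1: float
    n_cells: dict = field(default_factory=dict)
    analyzable: bool = True
    note: str = ""
    balance: list[BalanceReport] = field(default_factory=list)
    overlap: Optional[OverlapReport] = None
    dropped_covariates: list[str] = field(default_factory=list)

    def to_row(self) -> dict:
        return {
            "moderator": self.moderator,
            "outcome": self.outcome,
            "beta3": self.beta3.value,
            "beta3_ci_low": self.beta3.ci_low,
            "beta3_ci_high": self.beta3.ci_high,
            "beta3_p": self.beta3.p_value,
            "m_ate_0": self.m_ate_0.value,
            "m_ate_0_ci_low": self.m_ate_0.ci_low,
            "m_ate_0_ci_high": self.m_ate_0.ci_high,
            "m_ate_1": self.m_ate_1.value,
            "m_ate_1_ci_low": self.m_ate_1.ci_low,
            "m_ate_1_ci_high": self.m_ate_1.ci_high,
            "ame_0": self.ame_0,
            "ame_1": self.ame_1,
            "analyzable": self.analyzable,
            "note": self.note,
        }


def weighted_mean_difference(y, groups, weights=None) -> float:
    """Weighted mean of y in group 1 minus weighted mean in group 0."""
    y = np.asarray(y, dtype=float)
    g = np.asarray(groups, dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    return weighted_mean(y[g == 1], w[g == 1]) - weighted_mean(y[g == 0], w[g == 0])


def _drop_aliased(X: pd.DataFrame, protected: Sequence[str]) -> tuple[pd.DataFrame, list[str]]:
    """Drop adjustment columns that are constant or collinear with the rest."""
    dropped: list[str] = []
    cols = list(X.columns)
    for col in cols:
        if col in protected:
            continue
        x = X[col].to_numpy(dtype=float)
        if np.all(x == x[0]):
            dropped.append(col)
    X = X.drop(columns=dropped)
    # collinearity: greedy rank check on the remainder
    while np.linalg.matrix_rank(X.to_numpy(dtype=float)) < X.shape[1]:
        for col in reversed(list(X.columns)):
            if col in protected:
                continue
            trial = X.drop(columns=[col])
            if np.linalg.matrix_rank(trial.to_numpy(dtype=float)) == trial.shape[1]:
                dropped.append(col)
                X = trial
                break
        else:
            raise ValueError("design matrix rank-deficient in protected columns")
    return X, dropped


def fit_weighted_interaction(
    frame: pd.DataFrame,
    weights,
    outcome: str,
    treatment: str,
    moderator: str,
    adjust: Sequence[str] = (),
    cov_type: str = "HC3",
) -> ModerationResult:
    """Weighted least squares of Y on X, M, X*M (+ adjustment covariates).

    Uses heteroskedasticity-robust sandwich standard errors (HC3 by
    default: the weights are estimated and the per-level subsets can be
    small relative to the adjustment set) and normal-approximation 95%
    CIs.  Aliased adjustment covariates are
    dropped with a warning; a moderator identical (or complementary) to
    the treatment is refused, as is any empty treatment x moderator cell.
    """
    y = np.asarray(frame[outcome], dtype=float)
    x = np.asarray(frame[treatment], dtype=float)
    m = np.asarray(frame[moderator], dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)

    n_cells = {
        (ti, mi): int(((x == ti) & (m == mi)).sum()) for ti in (0, 1) for mi in (0, 1)
    }
    if np.array_equal(x, m) or np.array_equal(x, 1 - m):
        raise ValueError("moderator is aliased with the treatment")
    if any(v == 0 for v in n_cells.values()):
        raise ValueError(f"empty treatment x moderator cell: {n_cells}")

    design = pd.DataFrame(
        {"const": 1.0, "X": x, "M": m, "X:M": x * m}, index=frame.index
    )
    for cov in adjust:
        design[cov] = pd.to_numeric(frame[cov], errors="coerce").astype(float)
    design, dropped = _drop_aliased(design, protected=("const", "X", "M", "X:M"))
    if dropped:
        warnings.warn(f"dropped aliased adjustment covariates: {dropped}")

    with warnings.catch_warnings():
        # HC3 rescales residuals by 1/(1-h); saturated rows (leverage 1)
        # in very small subsets produce non-finite variances
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sm.WLS(y, design, weights=w).fit(cov_type=cov_type)
        if cov_type == "HC3" and not np.isfinite(res.bse[["X", "M", "X:M"]]).all():
            warnings.warn(
                "HC3 variance non-finite (saturated rows); falling back to HC1"
            )
            res = sm.WLS(y, design, weights=w).fit(cov_type="HC1")
    params = res.params
    conf = res.conf_int(alpha=0.05)
    cov_p = res.cov_params()

    def est(name: str) -> Estimate:
        return Estimate(
            float(params[name]),
            float(conf.loc[name, 0]),
            float(conf.loc[name, 1]),
            float(res.pvalues[name]),
        )

    b1, b3 = float(params["X"]), float(params["X:M"])
    var_sum = float(
        cov_p.loc["X", "X"] + cov_p.loc["X:M", "X:M"] + 2.0 * cov_p.loc["X", "X:M"]
    )
    se_sum = np.sqrt(max(var_sum, 0.0))
    z = 1.959963984540054
    mate1 = Estimate(b1 + b3, b1 + b3 - z * se_sum, b1 + b3 + z * se_sum)

    return ModerationResult(
        moderator=moderator,
        outcome=outcome,
        beta0=est("const"),
        beta1=est("X"),
        beta2=est("M"),
        beta3=est("X:M"),
        m_ate_0=est("X"),
        m_ate_1=mate1,
        ame_0=b1,
        ame_1=b1 + b3,
        n_cells={f"X{t_}M{m_}": v for (t_, m_), v in n_cells.items()},
        dropped_covariates=dropped,
    )


def average_marginal_effect(result: ModerationResult, level: int) -> float:
    """Mean derivative of predicted Y w.r.t. X within a moderator level.

    For the linear interaction specification this is b1 + b3 * level.
    """
    if level not in (0, 1):
        raise ValueError("moderator level must be 0 or 1")
    return result.beta1.value + result.beta3.value * level


def default_covariates(
    columns: Sequence[str],
    treatment: str,
    moderator: str,
    demographics: Sequence[str] = (
        "age",
        "female",
        "bmi",
        "physically_active",
        "walking_aid",
        "fall_history",
    ),
    condition_prefixes: Sequence[str] = (),
) -> list[str]:
    """Adjustment set: demographics, conditions, and all concomitant drug
    classes except the treatment and the moderator under examination."""
    from ._lexicon_data import CONDITIONS, DRUG_CLASSES

    covs = [c for c in demographics if c in columns]
    covs += [c for c in CONDITIONS if c in columns]
    covs += [d for d in DRUG_CLASSES if d in columns and d not in (treatment, moderator)]
    return covs


def run_single_moderator(
    frame: pd.DataFrame,
    moderator: str,
    treatment: str = "statin",
    outcome: str = "gsr",
    covariates: Optional[Sequence[str]] = None,
    ps_config: Optional[PSModelConfig] = None,
    threshold: float = BALANCE_THRESHOLD,
) -> ModerationResult:
    """The five-step moderation analysis for one candidate moderator.

    1. overlap screen across the four treatment x moderator cells;
    2. propensity fit separately within each moderator level;
    3. balance diagnostics (SMD, KS at the 0.20 threshold) per level;
    4. PS-weighted covariate-adjusted interaction fit on the pooled rows;
    5. tabulated ModerationResult with diagnostics attached.
    """
    if moderator == treatment:
        raise ValueError("treatment cannot moderate itself")
    if covariates is None:
        covariates = default_covariates(frame.columns, treatment, moderator)

    overlap, trimmed = screen_overlap(frame, treatment, moderator, covariates)
    if not overlap.analyzable:
        return _non_analyzable(moderator, outcome, "empty treatment x moderator cell", overlap)

    weights = np.ones(len(trimmed))
    balance_reports = []
    m = np.asarray(trimmed[moderator], dtype=float)
    for level in (0, 1):
        mask = m == level
        sub = trimmed.loc[mask]
        try:
            ps, _diag = fit_propensity(sub, treatment, covariates, ps_config)
        except ValueError as exc:
            return _non_analyzable(moderator, outcome, str(exc), overlap)
        truncate = (ps_config or PSModelConfig()).weight_truncate
        w = ate_weights(
            ps, np.asarray(sub[treatment], dtype=float), truncate_quantile=truncate
        )
        weights[mask] = w
        design, expanded = prepare_covariates(sub, covariates)
        design = design.assign(**{treatment: sub[treatment].to_numpy(dtype=float)})
        balance_reports.append(
            balance_table(design, treatment, expanded, w, threshold, moderator_level=level)
        )

    # adjust on the imputed design so rows with missing covariates stay in
    full_design, expanded = prepare_covariates(trimmed, covariates)
    fit_frame = full_design.assign(
        **{
            outcome: trimmed[outcome].to_numpy(dtype=float),
            treatment: trimmed[treatment].to_numpy(dtype=float),
            moderator: trimmed[moderator].to_numpy(dtype=float),
        }
    )
    result = fit_weighted_interaction(
        fit_frame, weights, outcome, treatment, moderator, adjust=expanded
    )
    result.balance = balance_reports
    result.overlap = overlap
    return result


def _non_analyzable(moderator, outcome, note, overlap) -> ModerationResult:
    nan_est = Estimate(np.nan, np.nan, np.nan, np.nan)
    return ModerationResult(
        moderator=moderator,
        outcome=outcome,
        beta0=nan_est,
        beta1=nan_est,
        beta2=nan_est,
        beta3=nan_est,
        m_ate_0=nan_est,
        m_ate_1=nan_est,
        ame_0=np.nan,
        ame_1=np.nan,
        analyzable=False,
        note=note,
        overlap=overlap,
    )


def run_all_moderators(
    frame: pd.DataFrame,
    moderators: Sequence[str],
    treatment: str = "statin",
    outcome: str = "gsr",
    ps_config: Optional[PSModelConfig] = None,
    threshold: float = BALANCE_THRESHOLD,
) -> list[ModerationResult]:
    """Run the five-step procedure for every candidate moderator.

    Moderators that cannot be analyzed (aliasing with treatment, empty
    cells) are reported as non-analyzable rows, never silently dropped.
    No multiplicity correction is applied to the per-moderator p-values.
    """
    results = []
    for mod in moderators:
        if mod == treatment:
            results.append(
                _non_analyzable(mod, outcome, "moderator identical to treatment", None)
            )
            continue
        try:
            results.append(
                run_single_moderator(
                    frame, mod, treatment, outcome, None, ps_config, threshold
                )
            )
        except ValueError as exc:
            results.append(_non_analyzable(mod, outcome, str(exc), None))
    return results


def run_stratified(
    frame: pd.DataFrame,
    stratum: str,
    moderators: Sequence[str],
    treatment: str = "statin",
    outcome: str = "gsr",
    ps_config: Optional[PSModelConfig] = None,
    threshold: float = BALANCE_THRESHOLD,
) -> dict[int, list[ModerationResult]]:
    """Repeat the full per-moderator analysis within each stratum level."""
    s = np.asarray(frame[stratum], dtype=float)
    out: dict[int, list[ModerationResult]] = {}
    for level in sorted(np.unique(s)):
        sub = frame.loc[s == level]
        out[int(level)] = run_all_moderators(
            sub, moderators, treatment, outcome, ps_config, threshold
        )
    return out


def results_to_frame(results: Sequence[ModerationResult]) -> pd.DataFrame:
    """Tabulate moderation results, one row per moderator."""
    return pd.DataFrame([r.to_row() for r in results]).set_index("moderator")
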