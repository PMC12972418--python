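"""Omitted-variable sensitivity analysis.

Maps how an unobserved confounder would shift the estimated moderated
treatment effect and its p-value within one moderator level.  For each
grid cell (SMD, rho) a synthetic standard-normal covariate is drawn
independently of the observed covariates, mean-shifted between the
treatment arms to reach the target between-arm SMD (x-axis) and
correlated with the outcome residual at the target rho (y-axis,
Cholesky-style mixing).  The propensity model is then re-estimated with
the simulated confounder included, the outcome model re-fit, and the
adjusted effect and p-value recorded, averaged over replicates.
Observed covariates' own (SMD, correlation) coordinates are attached as
markers so the grid can be read against what was actually measured.

This is a transparent simulate-augment-refit scheme with the same
inputs and outputs (axes, contours, covariate markers) as published
omitted-variable tooling; it does not reproduce any package's internal
algorithm verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .balance import smd
from .propensity import PSModelConfig, ate_weights, fit_propensity, prepare_covariates

__all__ = ["SensitivityGrid", "simulate_confounder", "sensitivity_grid"]

DEFAULT_SMD_GRID = tuple(np.round(np.arange(0.0, 0.31, 0.05), 2))
DEFAULT_RHO_GRID = tuple(np.round(np.arange(0.0, 0.31, 0.05), 2))


@dataclass
class SensitivityGrid:
    """Adjusted-effect and p-value surfaces over confounder strength."""

    smd_axis: np.ndarray  # confounder-treatment effect size (SMD)
    rho_axis: np.ndarray  # confounder-outcome correlation
    effects: np.ndarray  # shape (len(smd_axis), len(rho_axis)), cm/s
    p_values: np.ndarray
    baseline_effect: float
    baseline_p: float
    markers: pd.DataFrame  # observed covariates' (smd, rho) coordinates
    failed_cells: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.smd_axis):
            for j, r in enumerate(self.rho_axis):
                rows.append(
                    {
                        "confounder_smd": float(s),
                        "confounder_rho": float(r),
                        "adjusted_effect": float(self.effects[i, j]),
                        "adjusted_p": float(self.p_values[i, j]),
                    }
                )
        return pd.DataFrame(rows)


def simulate_confounder(
    treatment,
    outcome,
    target_smd: float,
    target_rho: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw a synthetic unobserved confounder with prescribed strength.

    Independent of observed covariates by construction; correlated with
    the treatment-residualized outcome at ``target_rho`` and mean-shifted
    between arms to a between-arm SMD of ``target_smd`` (the shift is
    constant within arm, so within-arm variances — and hence the SMD
    denominator — are untouched).
    """
    if target_smd < 0:
        raise ValueError("target SMD must be non-negative")
    if not -1.0 < target_rho < 1.0:
        raise ValueError("target rho must lie in (-1, 1)")
    t = np.asarray(treatment, dtype=float)
    y = np.asarray(outcome, dtype=float)
    n = len(t)
    # residualize the outcome on treatment so the arm shift cannot feed
    # back into the achieved correlation
    resid = y.copy()
    for arm in (0, 1):
        mask = t == arm
        if mask.any():
            resid[mask] = y[mask] - y[mask].mean()
    sd_resid, sd_y = resid.std(), y.std()
    z = resid / sd_resid if sd_resid > 0 else np.zeros(n)
    # exact in-sample construction: orthogonalize the noise against z and
    # standardize both components, so the achieved correlation is the
    # mixing weight itself rather than its expectation
    e = rng.normal(0.0, 1.0, n)
    for arm in (0, 1):  # zero per-arm means: the SMD comes from the shift alone
        mask = t == arm
        if mask.any():
            e[mask] -= e[mask].mean()
    if sd_resid > 0:
        e = e - (e @ z) / (z @ z) * z
    e_sd = e.std()
    e = e / e_sd if e_sd > 0 else e
    # the confounder is mixed with the residual, but the target is its
    # correlation with the outcome itself: rescale the mixing weight by
    # sd_y / sd_resid so corr(U, Y) hits target_rho
    alpha = target_rho * (sd_y / sd_resid) if sd_resid > 0 else 0.0
    if abs(alpha) >= 1.0:
        raise ValueError(
            f"target rho {target_rho} infeasible: outcome residual explains too "
            "little outcome variance"
        )
    u = alpha * z + np.sqrt(1.0 - alpha**2) * e
    # pooled within-arm SD of u sets the SMD denominator; the constant
    # per-arm shift leaves within-arm variances (and the achieved rho
    # contribution of z) untouched
    v1 = u[t == 1].var() if (t == 1).any() else 0.0
    v0 = u[t == 0].var() if (t == 0).any() else 0.0
    pooled_sd = np.sqrt((v1 + v0) / 2.0)
    u = u + target_smd * pooled_sd * t
    return u


def sensitivity_grid(
    frame: pd.DataFrame,
    treatment: str,
    outcome: str,
    covariates: Sequence[str],
    ps_config: Optional[PSModelConfig] = None,
    smd_grid: Sequence[float] = DEFAULT_SMD_GRID,
    rho_grid: Sequence[float] = DEFAULT_RHO_GRID,
    replicates: int = 25,
    rng: Optional[np.random.Generator] = None,
) -> SensitivityGrid:
    """Compute the omitted-variable sensitivity surface for one level table.

    ``frame`` holds one moderator level.  For every (SMD, rho) cell the
    simulated confounder joins the covariate set for both the propensity
    re-fit and the outcome re-fit; the recorded effect is the PS-weighted
    covariate-adjusted treatment coefficient.  Per-cell failures are
    recorded and the grid completes.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = rng or np.random.default_rng(0)
    ps_config = ps_config or PSModelConfig(method="logistic")

    base_effect, base_p = _weighted_effect(frame, treatment, outcome, covariates, ps_config)

    t = np.asarray(frame[treatment], dtype=float)
    y = np.asarray(frame[outcome], dtype=float)
    markers = []
    design, expanded = prepare_covariates(frame, covariates)
    for cov in expanded:
        x = np.asarray(design[cov], dtype=float)
        vals = np.unique(x)
        kind = "binary" if np.isin(vals, (0.0, 1.0)).all() else "continuous"
        s = smd(x[t == 1], x[t == 0], kind=kind)
        r = abs(float(np.corrcoef(x, y)[0, 1])) if x.std() > 0 else 0.0
        markers.append({"covariate": cov, "smd": s, "rho": r})

    smd_axis = np.asarray(smd_grid, dtype=float)
    rho_axis = np.asarray(rho_grid, dtype=float)
    effects = np.full((len(smd_axis), len(rho_axis)), np.nan)
    p_values = np.full_like(effects, np.nan)
    failed = []
    for i, s_target in enumerate(smd_axis):
        for j, r_target in enumerate(rho_axis):
            cell_effects, cell_ps = [], []
            for _ in range(replicates):
                try:
                    u = simulate_confounder(t, y, float(s_target), float(r_target), rng)
                    aug = frame.copy()
                    aug["_u"] = u
                    eff, p = _weighted_effect(
                        aug, treatment, outcome, list(covariates) + ["_u"], ps_config
                    )
                    cell_effects.append(eff)
                    cell_ps.append(p)
                except Exception as exc:
                    failed.append((float(s_target), float(r_target), str(exc)))
            if cell_effects:
                effects[i, j] = float(np.mean(cell_effects))
                p_values[i, j] = float(np.mean(cell_ps))
    return SensitivityGrid(
        smd_axis=smd_axis,
        rho_axis=rho_axis,
        effects=effects,
        p_values=p_values,
        baseline_effect=base_effect,
        baseline_p=base_p,
        markers=pd.DataFrame(markers),
        failed_cells=failed,
    )


def _weighted_effect(
    frame: pd.DataFrame,
    treatment: str,
    outcome: str,
    covariates: Sequence[str],
    ps_config: PSModelConfig,
) -> tuple[float, float]:
    """PS-weighted covariate-adjusted treatment effect within one level."""
    ps, _ = fit_propensity(frame, treatment, covariates, ps_config)
    t = np.asarray(frame[treatment], dtype=float)
    w = ate_weights(ps, t, truncate_quantile=ps_config.weight_truncate)
    design, expanded = prepare_covariates(frame, covariates)
    X = sm.add_constant(
        pd.concat([pd.Series(t, index=frame.index, name="X"), design[expanded]], axis=1)
    )
    keep = ["const", "X"] + [c for c in expanded if X[c].nunique() > 1]
    res = sm.WLS(np.asarray(frame[outcome], dtype=float), X[keep], weights=w).fit(
        cov_type="HC3"
    )
    return float(res.params["X"]), float(res.pvalues["X"])
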