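"""Outcome derivation and data-consistency checks.

Gait speed reserve (GSR) is the headroom between maximum and usual gait
speed, in cm/s.  The exclusion flow mirrors the study design: age >= 60,
complete gait measurements, complete medication history — applied in
that order, with each excluded row attributed to the first criterion it
trips; because criteria can overlap, the ledger also reports the full
overlap matrix.  Outlier screening follows the descriptive practice of
histogram inspection with Sturges' binning plus plausibility bounds;
flagged values are reported for review, never removed automatically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "derive_gsr",
    "apply_exclusions",
    "screen_outliers",
    "sturges_bins",
    "ExclusionLedger",
    "OutlierReport",
    "DEFAULT_PLAUSIBILITY_BOUNDS",
]

DEFAULT_PLAUSIBILITY_BOUNDS = {
    "bmi": (10.0, 70.0),
    "usual_speed": (5.0, 250.0),
    "max_speed": (5.0, 350.0),
    "age": (18.0, 120.0),
    "gsr": (-50.0, 200.0),
}

GSR_TOLERANCE = 1e-9  # negative reserve beyond this is flagged, not dropped


def derive_gsr(usual, maximum):
    """Gait speed reserve: maximum minus usual gait speed (cm/s).

    Positive by convention (reserve above usual pace).  Non-positive
    speeds are invalid inputs and raise; row-level exclusion of such
    records is handled by :func:`apply_exclusions`.
    """
    u = np.asarray(usual, dtype=float)
    m = np.asarray(maximum, dtype=float)
    if np.any(u[~np.isnan(u)] <= 0) or np.any(m[~np.isnan(m)] <= 0):
        raise ValueError("gait speeds must be positive")
    return m - u


@dataclass
class ExclusionLedger:
    """Counts per first-trigger exclusion reason plus the overlap matrix."""

    n_before: int
    n_after: int
    counts: dict = field(default_factory=dict)  # reason -> n (first trigger)
    overlap: pd.DataFrame | None = None  # criteria x criteria joint counts
    reasons: pd.Series | None = None  # per excluded row

    def to_dict(self) -> dict:
        return {
            "n_before": self.n_before,
            "n_after": self.n_after,
            "counts": dict(self.counts),
            "overlap": None if self.overlap is None else self.overlap.to_dict(),
        }


def apply_exclusions(
    frame: pd.DataFrame,
    min_age: float = 60.0,
    med_text_col: str = "med_text",
) -> tuple[pd.DataFrame, ExclusionLedger]:
    """Apply the sequential inclusion filters and account for every row.

    Order: (1) age >= min_age; (2) complete usual and maximum gait
    speed; (3) complete medication history.  Each excluded row gets the
    first reason that applies; the ledger's overlap matrix shows joint
    trigger counts since the criteria are not mutually exclusive.
    Idempotent: a second application excludes nothing.
    """
    age_bad = frame["age"].isna() | (frame["age"] < min_age)
    gait_bad = frame["usual_speed"].isna() | frame["max_speed"].isna()
    if med_text_col in frame:
        med = frame[med_text_col]
        med_bad = med.isna() | (med.astype(str).str.strip() == "")
    else:  # no text column: medication completeness not assessable here
        med_bad = pd.Series(False, index=frame.index)

    criteria = {"age": age_bad, "gait": gait_bad, "medication": med_bad}
    reasons = pd.Series(pd.NA, index=frame.index, dtype="object")
    for name, mask in criteria.items():  # first-trigger attribution
        reasons[mask & reasons.isna()] = name

    excluded = reasons.notna()
    overlap = pd.DataFrame(
        {
            a: {b: int((criteria[a] & criteria[b]).sum()) for b in criteria}
            for a in criteria
        }
    )
    included = frame.loc[~excluded].copy()
    if {"usual_speed", "max_speed"}.issubset(included.columns):
        gsr = derive_gsr(included["usual_speed"], included["max_speed"])
        included["gsr"] = gsr
        included["gsr_negative_flag"] = gsr < -GSR_TOLERANCE
    ledger = ExclusionLedger(
        n_before=len(frame),
        n_after=len(included),
        counts={name: int((reasons == name).sum()) for name in criteria},
        overlap=overlap,
        reasons=reasons[excluded],
    )
    return included, ledger


def sturges_bins(n: int) -> int:
    """Sturges' histogram bin count: ceil(log2(n)) + 1."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return math.ceil(math.log2(n)) + 1


@dataclass
class OutlierReport:
    flags: pd.DataFrame  # columns: field, value, bound_low, bound_high
    histograms: dict = field(default_factory=dict)  # field -> (counts, edges)

    @property
    def n_flagged(self) -> int:
        return len(self.flags)


def screen_outliers(
    frame: pd.DataFrame,
    fields=None,
    bounds: dict | None = None,
) -> OutlierReport:
    """Flag biologically implausible values for manual review.

    Builds Sturges-binned histograms for each numeric field and lists
    values outside the configured plausibility bounds.  Removal is left
    to the caller — an explicit, separate action.
    """
    bounds = {**DEFAULT_PLAUSIBILITY_BOUNDS, **(bounds or {})}
    if fields is None:
        fields = [f for f in bounds if f in frame.columns]
    rows = []
    histograms = {}
    for f in fields:
        x = pd.to_numeric(frame[f], errors="coerce")
        observed = x.dropna()
        if observed.empty:
            continue
        histograms[f] = np.histogram(observed, bins=sturges_bins(len(observed)))
        lo, hi = bounds.get(f, (-np.inf, np.inf))
        bad = x.notna() & ((x < lo) | (x > hi))
        for idx, val in x[bad].items():
            rows.append({"row": idx, "field": f, "value": float(val), "bound_low": lo, "bound_high": hi})
    flags = pd.DataFrame(rows, columns=["row", "field", "value", "bound_low", "bound_high"])
    return OutlierReport(flags=flags, histograms=histograms)
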