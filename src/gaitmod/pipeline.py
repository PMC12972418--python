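"""End-to-end pipeline: simulate/load -> annotate -> QC -> moderate -> report.

Ties the stages into a reproducible run driven by a YAML config, writing
publication-style outputs (baseline-characteristics table with an SMD
column, moderation results table, balance reports, sensitivity grids)
plus a JSON manifest recording configuration, seeds and versions.
"""

from __future__ import annotations

import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._lexicon_data import CONDITIONS, DRUG_CLASSES
from .annotation import (
    Lexicon,
    annotate_conditions,
    annotate_medications,
    default_condition_lexicon,
    default_drug_lexicon,
)
from .balance import smd
from .cohort import DEMOGRAPHICS, CohortSpec, generate_cohort, inject_missingness
from .moderation import ModerationResult, results_to_frame, run_all_moderators
from .propensity import PSModelConfig
from .qc import apply_exclusions, screen_outliers
from .sensitivity import sensitivity_grid

logger = logging.getLogger("gaitmod")

__all__ = [
    "RunConfig",
    "run_pipeline",
    "annotate_cohort",
    "make_table1",
    "make_interaction_plot_data",
]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    outdir: str = "gaitmod_run"
    seed: int = 0
    n: int = 5519
    threshold: float = 0.85
    treatment: str = "statin"
    outcome: str = "gsr"
    moderators: Sequence[str] = field(
        default_factory=lambda: [d for d in DRUG_CLASSES if d != "statin"]
    )
    ps_method: str = "logistic"
    ps_max_trees: int = 300
    strata: Sequence[str] = ()
    sensitivity_moderator: Optional[str] = None  # e.g. "aspirin"
    sensitivity_replicates: int = 25
    missingness: dict = field(
        default_factory=lambda: {"gait": 0.058, "med_text": 0.0, "bmi": 0.03}
    )
    drug_lexicon: Optional[str] = None  # CSV path; default built-in
    condition_lexicon: Optional[str] = None
    cohort_csv: Optional[str] = None  # load instead of simulating

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        for attr in ("drug_lexicon", "condition_lexicon", "cohort_csv"):
            p = getattr(cfg, attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{attr}: {p}")
        return cfg


def annotate_cohort(
    frame: pd.DataFrame,
    drug_lexicon: Optional[Lexicon] = None,
    condition_lexicon: Optional[Lexicon] = None,
    threshold: float = 0.85,
) -> pd.DataFrame:
    """Annotate med_text / comorbid_text into binary flag columns.

    Returns a frame indexed like the input with one column per drug
    class and condition, plus ``med_annotation_missing`` marking records
    whose medication history was absent (flagged for exclusion).
    """
    drug_lexicon = drug_lexicon or default_drug_lexicon()
    condition_lexicon = condition_lexicon or default_condition_lexicon()
    rows = []
    for _, row in frame.iterrows():
        med_report = annotate_medications(row.get("med_text"), drug_lexicon, threshold)
        cond_report = annotate_conditions(row.get("comorbid_text"), condition_lexicon, threshold)
        entry = {d: float(d in med_report.codes) for d in DRUG_CLASSES}
        entry.update({c: float(c in cond_report.codes) for c in CONDITIONS})
        entry["med_annotation_missing"] = float(med_report.excluded)
        rows.append(entry)
    return pd.DataFrame(rows, index=frame.index)


def make_table1(
    frame: pd.DataFrame,
    treatment: str = "statin",
    continuous: Sequence[str] = ("age", "bmi"),
    binary: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Baseline characteristics by treatment arm with an SMD column.

    Continuous rows report mean (SD) per group; binary rows report
    percentages.  The SMD column applies the same standardized mean
    difference operation used by the balance diagnostics.
    """
    t = np.asarray(frame[treatment], dtype=float)
    if binary is None:
        binary = [
            c
            for c in DEMOGRAPHICS + CONDITIONS + DRUG_CLASSES
            if c in frame.columns and c not in continuous and c != treatment
        ]
    rows = []
    for var in list(continuous) + list(binary):
        x = pd.to_numeric(frame[var], errors="coerce").to_numpy(dtype=float)
        ok = ~np.isnan(x)
        a, b = x[ok & (t == 1)], x[ok & (t == 0)]
        kind = "continuous" if var in continuous else "binary"
        value = smd(a, b, kind=kind)
        if kind == "continuous":
            rows.append(
                {
                    "variable": var,
                    "overall": f"{x[ok].mean():.2f} ({x[ok].std(ddof=1):.2f})",
                    "no_treatment": f"{b.mean():.2f} ({b.std(ddof=1):.2f})",
                    "treatment": f"{a.mean():.2f} ({a.std(ddof=1):.2f})",
                    "smd": round(value, 2),
                }
            )
        else:
            rows.append(
                {
                    "variable": var,
                    "overall": f"{100 * x[ok].mean():.1f}%",
                    "no_treatment": f"{100 * b.mean():.1f}%",
                    "treatment": f"{100 * a.mean():.1f}%",
                    "smd": round(value, 2),
                }
            )
    return pd.DataFrame(rows).set_index("variable")


def make_interaction_plot_data(result: ModerationResult) -> pd.DataFrame:
    """Cell means (treatment x moderator) with 95% CIs, long format.

    Predicted outcomes from the fitted interaction coefficients at the
    four design cells; suitable for an interaction plot.  Refuses a
    non-analyzable result or constant moderator.
    """
    if not result.analyzable:
        raise ValueError("result is not analyzable")
    if any(v == 0 for v in result.n_cells.values()):
        raise ValueError("moderator or treatment constant: empty design cell")
    b0, b1 = result.beta0, result.beta1
    b2, b3 = result.beta2, result.beta3
    rows = []
    for x in (0, 1):
        for m in (0, 1):
            mean = b0.value + b1.value * x + b2.value * m + b3.value * x * m
            half = sum(
                (e.ci_high - e.ci_low) / 2 * flag
                for e, flag in ((b0, 1), (b1, x), (b2, m), (b3, x * m))
            )
            rows.append(
                {
                    "treatment": x,
                    "moderator_level": m,
                    "mean": mean,
                    "ci_low": mean - half,
                    "ci_high": mean + half,
                    "n": result.n_cells.get(f"X{x}M{m}", np.nan),
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns a dict of output paths.

    Stages: simulate (or load) -> annotate -> exclusions/QC ->
    baseline table -> per-moderator five-step moderation analysis ->
    optional sensitivity grid -> manifest.  Any stage failure removes
    partial outputs and re-raises with a stage tag.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    stage = "setup"
    try:
        rng = np.random.default_rng(config.seed + 1)
        drug_lex = (
            Lexicon.from_csv(config.drug_lexicon)
            if config.drug_lexicon
            else default_drug_lexicon()
        )
        cond_lex = (
            Lexicon.from_csv(config.condition_lexicon)
            if config.condition_lexicon
            else default_condition_lexicon()
        )

        stage = "simulate"
        if config.cohort_csv:
            cohort = pd.read_csv(config.cohort_csv)
            logger.info("loaded cohort: %d records", len(cohort))
        else:
            spec = CohortSpec(n=config.n, seed=config.seed)
            cohort = generate_cohort(spec, drug_lexicon=drug_lex, condition_lexicon=cond_lex)
            cohort = inject_missingness(cohort, config.missingness, rng)
            logger.info("simulated cohort: %d records", len(cohort))
        _write(cohort, outdir / "cohort.csv", outputs, "cohort")

        stage = "annotate"
        flags = annotate_cohort(cohort, drug_lex, cond_lex, config.threshold)
        annotated = cohort[
            [c for c in cohort.columns if c not in flags.columns]
        ].join(flags)
        _write(annotated, outdir / "annotated.csv", outputs, "annotated")
        logger.info("annotated %d records", len(annotated))

        stage = "qc"
        included, ledger = apply_exclusions(annotated)
        outliers = screen_outliers(included)
        with open(outdir / "exclusions.json", "w", encoding="utf-8") as fh:
            json.dump(ledger.to_dict(), fh, indent=2)
        outputs["exclusions"] = str(outdir / "exclusions.json")
        _write(outliers.flags, outdir / "outlier_flags.csv", outputs, "outliers")
        logger.info(
            "exclusions: %s -> %d analyzable", ledger.counts, ledger.n_after
        )

        stage = "table1"
        table1 = make_table1(included, config.treatment)
        _write(table1, outdir / "table1.csv", outputs, "table1", index=True)

        stage = "moderate"
        ps_config = PSModelConfig(
            method=config.ps_method, max_trees=config.ps_max_trees, seed=config.seed
        )
        results = run_all_moderators(
            included,
            config.moderators,
            config.treatment,
            config.outcome,
            ps_config,
        )
        table2 = results_to_frame(results)
        _write(table2, outdir / "table2.csv", outputs, "table2", index=True)
        with open(outdir / "table2.json", "w", encoding="utf-8") as fh:
            json.dump(
                json.loads(table2.reset_index().to_json(orient="records")), fh, indent=2
            )
        balance_dir = outdir / "balance"
        balance_dir.mkdir(exist_ok=True)
        for res in results:
            for rep in res.balance:
                rep.table.to_csv(
                    balance_dir / f"{res.moderator}_level{rep.moderator_level}.csv"
                )
        outputs["balance_dir"] = str(balance_dir)
        logger.info("moderation analysis: %d moderators", len(results))

        stage = "sensitivity"
        if config.sensitivity_moderator:
            mod = config.sensitivity_moderator
            for level in (0, 1):
                sub = included.loc[included[mod] == level]
                covs = [
                    c
                    for c in DEMOGRAPHICS + CONDITIONS + DRUG_CLASSES
                    if c in sub.columns and c not in (config.treatment, mod)
                ]
                grid = sensitivity_grid(
                    sub,
                    config.treatment,
                    config.outcome,
                    covs,
                    ps_config,
                    replicates=config.sensitivity_replicates,
                    rng=np.random.default_rng(config.seed + 100 + level),
                )
                _write(
                    grid.to_frame(),
                    outdir / f"sensitivity_{mod}_level{level}.csv",
                    outputs,
                    f"sensitivity_level{level}",
                )
            logger.info("sensitivity grids written for moderator %s", mod)

        stage = "manifest"
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "config": {
                k: (list(v) if isinstance(v, (tuple, list)) else v)
                for k, v in vars(config).items()
            },
            "n_included": int(len(included)),
            "outputs": outputs,
        }
        with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        outputs["manifest"] = str(outdir / "manifest.json")
        return outputs
    except Exception as exc:
        shutil.rmtree(outdir, ignore_errors=True)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _write(df: pd.DataFrame, path: Path, outputs: dict, key: str, index: bool = False) -> None:
    df.to_csv(path, index=index)
    outputs[key] = str(path)
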