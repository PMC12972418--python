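"""Tests for overlap screening, propensity estimation and ATE weights."""

import numpy as np
import pandas as pd
import pytest

from gaitmod import CohortSpec, generate_cohort, inject_missingness, smd
from gaitmod.balance import weighted_mean
from gaitmod.moderation import default_covariates
from gaitmod.propensity import (
    PSModelConfig,
    ate_weights,
    fit_propensity,
    prepare_covariates,
    screen_overlap,
)


class TestATEWeights:
    def test_formula(self):
        ps = np.array([0.5, 0.5, 0.8, 0.8])
        t = np.array([1.0, 0.0, 1.0, 0.0])
        w = ate_weights(ps, t, stabilize=False)
        np.testing.assert_allclose(w, [2.0, 2.0, 1.25, 5.0])

    def test_stabilized_weights_mean_one_per_arm(self, rng):
        ps = rng.uniform(0.1, 0.9, 200)
        t = (rng.random(200) < 0.4).astype(float)
        w = ate_weights(ps, t)
        assert weighted_mean(w[t == 1]) == pytest.approx(1.0)
        assert weighted_mean(w[t == 0]) == pytest.approx(1.0)

    def test_stabilization_preserves_weighted_mean_differences(self, rng):
        ps = rng.uniform(0.2, 0.8, 300)
        t = (rng.random(300) < 0.5).astype(float)
        y = rng.normal(0, 1, 300) + t
        raw = ate_weights(ps, t, stabilize=False)
        stab = ate_weights(ps, t, stabilize=True)
        d_raw = weighted_mean(y[t == 1], raw[t == 1]) - weighted_mean(y[t == 0], raw[t == 0])
        d_stab = weighted_mean(y[t == 1], stab[t == 1]) - weighted_mean(y[t == 0], stab[t == 0])
        assert d_raw == pytest.approx(d_stab)

    def test_rejects_degenerate_propensity(self):
        with pytest.raises(ValueError):
            ate_weights([0.0, 0.5], [1, 0])

    def test_six_row_hand_fixture_balances_covariate(self):
        # true ps depends only on x; weighting balances x between arms.
        # hand computation: treated weighted mean of x =
        #   (1*(1/.8) + 0*(1/.4)) / (1/.8 + 1/.4) = 1.25/3.75 = 1/3
        # control weighted mean of x =
        #   (1*(1/.2) + 0*(1/.6) + 0*(1/.6)) / (1/.2 + 1/.6 + 1/.6)
        #   = 5/8.3333 = 0.6  -> with both arms' duplicates below they agree
        frame = pd.DataFrame(
            {
                "t": [1, 1, 1, 0, 0, 0],
                "x": [1, 1, 0, 1, 0, 0],
                "ps": [0.8, 0.8, 0.4, 0.8, 0.4, 0.4],
            }
        )
        w = ate_weights(frame.ps.to_numpy(), frame.t.to_numpy(), stabilize=False)
        t = frame.t.to_numpy()
        m1 = weighted_mean(frame.x[t == 1], w[t == 1])
        m0 = weighted_mean(frame.x[t == 0], w[t == 0])
        # hand numbers: treated (1.25+1.25+0)/(1.25+1.25+2.5) = 2.5/5 = 0.5
        #               control (5+0+0)/(5+1.6667+1.6667) = 5/8.3333 = 0.6
        assert m1 == pytest.approx(0.5)
        assert m0 == pytest.approx(0.6)

    def test_true_propensity_weights_balance_in_expectation(self, rng):
        n = 20000
        x = (rng.random(n) < 0.5).astype(float)
        ps = 0.2 + 0.5 * x
        t = (rng.random(n) < ps).astype(float)
        w = ate_weights(ps, t, stabilize=False)
        m1 = weighted_mean(x[t == 1], w[t == 1])
        m0 = weighted_mean(x[t == 0], w[t == 0])
        assert abs(m1 - m0) < 0.03


class TestPrepareCovariates:
    def test_missingness_indicator_and_out_of_range_constant(self):
        frame = pd.DataFrame({"a": [1.0, 2.0, np.nan, 4.0], "b": [0, 1, 1, 0]})
        design, names = prepare_covariates(frame, ["a", "b"])
        assert names == ["a", "a_missing", "b"]
        assert design["a_missing"].tolist() == [0.0, 0.0, 1.0, 0.0]
        fill = design.loc[2, "a"]
        assert fill > 4.0  # strictly outside the observed range

    def test_no_missing_no_indicator(self):
        frame = pd.DataFrame({"a": [1.0, 2.0]})
        design, names = prepare_covariates(frame, ["a"])
        assert names == ["a"] and list(design.columns) == ["a"]


class TestFitPropensity:
    def test_single_class_treatment_rejected(self, analysis_cohort):
        sub = analysis_cohort[analysis_cohort.statin == 1]
        with pytest.raises(ValueError, match="single class"):
            fit_propensity(sub, "statin", ["age", "bmi"], PSModelConfig(method="logistic"))

    def test_independent_covariates_give_marginal_rate(self, rng):
        n = 3000
        frame = pd.DataFrame(
            {
                "t": (rng.random(n) < 0.3).astype(float),
                "x1": rng.normal(0, 1, n),
                "x2": (rng.random(n) < 0.5).astype(float),
            }
        )
        ps, _ = fit_propensity(frame, "t", ["x1", "x2"], PSModelConfig(method="logistic"))
        assert ps.mean() == pytest.approx(frame.t.mean(), abs=0.02)
        assert ps.std() < 0.05

    @pytest.mark.parametrize("method", ["logistic", "gbm"])
    def test_single_confounder_balanced_below_threshold(self, method, rng):
        n = 2000
        x = (rng.random(n) < 0.4).astype(float)
        t = (rng.random(n) < (0.15 + 0.45 * x)).astype(float)
        frame = pd.DataFrame({"t": t, "x": x, "z": rng.normal(0, 1, n)})
        config = PSModelConfig(method=method, max_trees=300, seed=0)
        ps, _ = fit_propensity(frame, "t", ["x", "z"], config)
        w = ate_weights(ps, t)
        pre = smd(x[t == 1], x[t == 0], kind="binary")
        post = smd(x[t == 1], x[t == 0], w[t == 1], w[t == 0], kind="binary")
        assert post < pre
        assert post < 0.20

    def test_full_cohort_confounders_balanced_by_logistic_ps(self):
        f = generate_cohort(CohortSpec(n=1500, seed=21), text=False)
        sub = f[f.aspirin == 0]
        covs = default_covariates(f.columns, "statin", "aspirin")
        ps, _ = fit_propensity(sub, "statin", covs, PSModelConfig(method="logistic"))
        w = ate_weights(ps, sub.statin.to_numpy())
        t = sub.statin.to_numpy()
        x = sub.hyperlipidemia.to_numpy()
        pre = smd(x[t == 1], x[t == 0], kind="binary")
        post = smd(x[t == 1], x[t == 0], w[t == 1], w[t == 0], kind="binary")
        assert post < pre and post < 0.20

    def test_missingness_indicator_balanced_after_weighting(self, rng):
        f = generate_cohort(CohortSpec(n=4000, seed=22), text=False)
        f = inject_missingness(f, {"bmi": 0.1}, rng, mar_by="statin", mar_ratio=2.0)
        covs = default_covariates(f.columns, "statin", "aspirin")
        sub = f[f.aspirin == 0]
        ps, diag = fit_propensity(sub, "statin", covs, PSModelConfig(method="logistic"))
        assert "bmi_missing" in diag["covariates"]
        w = ate_weights(ps, sub.statin.to_numpy())
        t = sub.statin.to_numpy()
        design, _ = prepare_covariates(sub, covs)
        ind = design["bmi_missing"].to_numpy()
        pre = smd(ind[t == 1], ind[t == 0], kind="binary")
        post = smd(ind[t == 1], ind[t == 0], w[t == 1], w[t == 0], kind="binary")
        assert post < 0.20 and post <= pre + 0.02

    def test_propensities_strictly_inside_unit_interval(self, analysis_cohort):
        covs = default_covariates(analysis_cohort.columns, "statin", "aspirin")
        ps, _ = fit_propensity(
            analysis_cohort, "statin", covs, PSModelConfig(method="logistic")
        )
        assert (ps > 0).all() and (ps < 1).all()


class TestScreenOverlap:
    def test_sex_restricted_drug_excludes_females(self):
        f = generate_cohort(CohortSpec(n=4000, seed=23), text=False)
        covs = default_covariates(f.columns, "statin", "five_alpha_reductase_inhibitor")
        report, trimmed = screen_overlap(
            f, "statin", "five_alpha_reductase_inhibitor", covs
        )
        excluded = {(c, lv) for c, lv, _ in report.excluded_levels}
        assert ("female", 1.0) in excluded
        assert trimmed.female.sum() == 0

    def test_fully_overlapping_cohort_no_exclusions(self):
        f = generate_cohort(CohortSpec(n=4000, seed=24), text=False)
        covs = ["age", "bmi", "hypertension", "diabetes"]
        report, trimmed = screen_overlap(f, "statin", "aspirin", covs)
        assert report.excluded_levels == []
        assert len(trimmed) == len(f)
        assert report.analyzable

    def test_disjoint_numeric_ranges_flagged(self, rng):
        n = 400
        t = np.repeat([0, 1], n // 2)
        m = np.tile([0, 1], n // 2)
        x = rng.normal(0, 1, n) + 50 * ((t == 1) & (m == 1))
        frame = pd.DataFrame({"t": t, "m": m, "x": x})
        report, _ = screen_overlap(frame, "t", "m", ["x"])
        assert report.flagged_numeric == ["x"]

    def test_empty_cell_marks_non_analyzable(self, rng):
        frame = pd.DataFrame(
            {"t": [0, 0, 1, 1], "m": [0, 0, 0, 0], "x": [1.0, 2.0, 3.0, 4.0]}
        )
        report, _ = screen_overlap(frame, "t", "m", ["x"])
        assert not report.analyzable
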