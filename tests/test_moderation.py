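"""Tests for the weighted interaction model and the moderator loop."""

import numpy as np
import pandas as pd
import pytest

from gaitmod import CohortSpec, generate_cohort
from gaitmod.moderation import (
    average_marginal_effect,
    fit_weighted_interaction,
    results_to_frame,
    run_all_moderators,
    run_single_moderator,
    run_stratified,
    weighted_mean_difference,
)
from gaitmod.pipeline import make_interaction_plot_data
from gaitmod.propensity import PSModelConfig

LOGISTIC = PSModelConfig(method="logistic")


def four_cell_frame(n_per_cell=5, noise=None, rng=None):
    rows = []
    for x in (0, 1):
        for m in (0, 1):
            for _ in range(n_per_cell):
                y = 10 + 2 * x + 1 * m + 5 * x * m
                rows.append({"x": x, "m": m, "y": float(y)})
    frame = pd.DataFrame(rows)
    if noise is not None:
        frame["y"] += noise
    return frame


class TestFitWeightedInteraction:
    def test_noiseless_exact_recovery(self):
        frame = four_cell_frame()
        res = fit_weighted_interaction(frame, None, "y", "x", "m")
        assert res.beta0.value == pytest.approx(10.0, abs=1e-10)
        assert res.beta1.value == pytest.approx(2.0, abs=1e-10)
        assert res.beta2.value == pytest.approx(1.0, abs=1e-10)
        assert res.beta3.value == pytest.approx(5.0, abs=1e-10)
        assert res.m_ate_0.value == pytest.approx(2.0, abs=1e-10)
        assert res.m_ate_1.value == pytest.approx(7.0, abs=1e-10)

    def test_mate_identity_holds_to_machine_precision(self, rng):
        frame = four_cell_frame(noise=rng.normal(0, 3, 20))
        w = rng.random(20) + 0.5
        res = fit_weighted_interaction(frame, w, "y", "x", "m")
        assert res.m_ate_1.value - res.m_ate_0.value == pytest.approx(
            res.beta3.value, abs=1e-12
        )
        assert res.m_ate_0.value == res.beta1.value

    def test_unit_weights_reproduce_raw_cell_mean_differences(self, rng):
        frame = four_cell_frame(n_per_cell=30, noise=rng.normal(0, 4, 120))
        res = fit_weighted_interaction(frame, None, "y", "x", "m")
        cells = frame.groupby(["m", "x"])["y"].mean()
        assert res.beta1.value == pytest.approx(cells[(0, 1)] - cells[(0, 0)])
        assert res.beta1.value + res.beta3.value == pytest.approx(
            cells[(1, 1)] - cells[(1, 0)]
        )
        # and beta1 equals the plain weighted mean difference within m = 0
        sub = frame[frame.m == 0]
        assert res.beta1.value == pytest.approx(
            weighted_mean_difference(sub.y, sub.x)
        )

    def test_moderator_aliased_with_treatment_refused(self):
        frame = four_cell_frame()
        frame["m2"] = frame["x"]
        with pytest.raises(ValueError, match="aliased"):
            fit_weighted_interaction(frame, None, "y", "x", "m2")

    def test_empty_cell_refused(self):
        frame = four_cell_frame()
        frame = frame[~((frame.x == 1) & (frame.m == 1))]
        with pytest.raises(ValueError, match="empty"):
            fit_weighted_interaction(frame, None, "y", "x", "m")

    def test_constant_adjustment_covariate_dropped_with_warning(self, rng):
        frame = four_cell_frame(n_per_cell=10, noise=rng.normal(0, 1, 40))
        frame["c"] = 1.0
        with pytest.warns(UserWarning, match="aliased"):
            res = fit_weighted_interaction(frame, None, "y", "x", "m", adjust=["c"])
        assert res.dropped_covariates == ["c"]


class TestAME:
    def test_closed_form(self, rng):
        frame = four_cell_frame(noise=rng.normal(0, 1, 20))
        res = fit_weighted_interaction(frame, None, "y", "x", "m")
        assert average_marginal_effect(res, 0) == res.beta1.value
        assert average_marginal_effect(res, 1) == res.beta1.value + res.beta3.value

    def test_agrees_with_finite_difference_on_predictions(self, rng):
        frame = four_cell_frame(n_per_cell=20, noise=rng.normal(0, 2, 80))
        res = fit_weighted_interaction(frame, None, "y", "x", "m")

        def predict(x, m):
            return (
                res.beta0.value
                + res.beta1.value * x
                + res.beta2.value * m
                + res.beta3.value * x * m
            )

        eps = 1e-6
        for level in (0, 1):
            fd = (predict(1.0 + eps, level) - predict(1.0, level)) / eps
            assert average_marginal_effect(res, level) == pytest.approx(fd, abs=1e-8)

    def test_no_interaction_equal_ames(self):
        frame = four_cell_frame()
        frame["y"] = 10 + 2 * frame.x + 1 * frame.m  # beta3 = 0
        res = fit_weighted_interaction(frame, None, "y", "x", "m")
        assert average_marginal_effect(res, 0) == pytest.approx(
            average_marginal_effect(res, 1), abs=1e-10
        )


class TestRunModerators:
    def test_recovers_generating_interaction(self):
        f = generate_cohort(CohortSpec(n=4000, seed=31, interaction=5.0), text=False)
        res = run_single_moderator(f, "aspirin", ps_config=LOGISTIC)
        assert res.analyzable
        assert res.beta3.ci_low <= 5.0 <= res.beta3.ci_high
        assert all(rep.all_pass for rep in res.balance)

    def test_moderator_identical_to_treatment_reported(self, analysis_cohort):
        results = run_all_moderators(
            analysis_cohort, ["statin", "aspirin"], ps_config=LOGISTIC
        )
        by_name = {r.moderator: r for r in results}
        assert not by_name["statin"].analyzable
        assert by_name["aspirin"].analyzable

    def test_full_moderator_sweep_emits_one_row_each(self, analysis_cohort):
        from gaitmod._lexicon_data import DRUG_CLASSES

        moderators = [d for d in DRUG_CLASSES if d != "statin"]
        results = run_all_moderators(analysis_cohort, moderators, ps_config=LOGISTIC)
        assert len(results) == 21
        table = results_to_frame(results)
        assert set(table.index) == set(moderators)
        # rare exposures at n = 2000 may be non-analyzable, but most run
        assert table.analyzable.sum() >= 15

    def test_other_level_permutation_leaves_result_unchanged(self):
        f = generate_cohort(CohortSpec(n=1500, seed=32), text=False).reset_index(drop=True)
        res_a = run_single_moderator(f, "aspirin", ps_config=LOGISTIC)
        # permute the rows of level 1 only; level-0 estimation must not move
        idx1 = f.index[f.aspirin == 1].to_numpy()
        perm = np.random.default_rng(0).permutation(idx1)
        g = f.copy()
        g.loc[idx1] = f.loc[perm].to_numpy()
        res_b = run_single_moderator(g, "aspirin", ps_config=LOGISTIC)
        assert res_a.beta3.value == pytest.approx(res_b.beta3.value, abs=1e-8)
        pd.testing.assert_frame_equal(
            res_a.balance[0].table, res_b.balance[0].table, check_exact=False
        )


class TestStratified:
    def test_constant_stratum_equals_unstratified(self, analysis_cohort):
        f = analysis_cohort.assign(one=1.0)
        strat = run_stratified(f, "one", ["aspirin"], ps_config=LOGISTIC)
        flat = run_all_moderators(f, ["aspirin"], ps_config=LOGISTIC)
        assert list(strat.keys()) == [1]
        assert strat[1][0].beta3.value == pytest.approx(flat[0].beta3.value)

    def test_both_ascvd_strata_analyzable(self, analysis_cohort):
        strat = run_stratified(analysis_cohort, "ascvd", ["aspirin"], ps_config=LOGISTIC)
        assert set(strat) == {0, 1}
        assert all(res[0].analyzable for res in strat.values())

    def test_effect_recovered_only_in_generating_stratum(self):
        # stratum 1 carries the interaction; stratum 0 is null
        f1 = generate_cohort(CohortSpec(n=3500, seed=33, interaction=8.0), text=False)
        f0 = generate_cohort(CohortSpec(n=3500, seed=34, interaction=0.0), text=False)
        f1["stratum"], f0["stratum"] = 1.0, 0.0
        f = pd.concat([f0, f1], ignore_index=True)
        strat = run_stratified(f, "stratum", ["aspirin"], ps_config=LOGISTIC)
        assert strat[1][0].beta3.p_value < 0.05
        assert strat[1][0].beta3.value > 3.0
        assert abs(strat[0][0].beta3.value) < 3.0


class TestInteractionPlotData:
    def test_noiseless_cell_means(self):
        frame = four_cell_frame()
        res = fit_weighted_interaction(frame, None, "y", "x", "m")
        data = make_interaction_plot_data(res)
        expected = {(0, 0): 10.0, (1, 0): 12.0, (0, 1): 11.0, (1, 1): 18.0}
        for _, row in data.iterrows():
            assert row["mean"] == pytest.approx(
                expected[(row.treatment, row.moderator_level)], abs=1e-9
            )
            assert row.ci_low <= row["mean"] <= row.ci_high

    def test_non_analyzable_refused(self, analysis_cohort):
        results = run_all_moderators(analysis_cohort, ["statin"], ps_config=LOGISTIC)
        with pytest.raises(ValueError):
            make_interaction_plot_data(results[0])
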