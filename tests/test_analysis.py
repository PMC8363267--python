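"""Analysis stage against closed forms and independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from synerk import (
    AnalysisError,
    auc_above_basal,
    fit_dose_response,
    pathway_contribution,
    robustness_importance,
    summation_test,
    temporal_sensitivity,
)
from synerk.analysis import _hill
from synerk.simulate import Trajectory, count_factor


def _make_traj(times, values, species="ppERK", volume=4.0):
    amounts = np.outer(values, [1.0]) * count_factor(volume)
    return Trajectory(
        times=np.asarray(times, float), amounts=amounts,
        species_names=(species,), volume=volume, method="ode",
    )


class TestAuc:
    def test_rectangle_closed_form(self):
        """10 nM above basal for 100 s integrates to 1000 nM·s."""
        t = np.arange(0.0, 801.0)
        y = np.full_like(t, 5.0)
        y[(t >= 400) & (t < 500)] += 10.0
        res = auc_above_basal(_make_traj(t, y), stim_onset=400.0)
        assert res.basal == pytest.approx(5.0)
        assert res.auc == pytest.approx(1000.0, rel=0.01)
        assert res.peak == pytest.approx(15.0)

    def test_alpha_transient_matches_quadrature(self):
        """AUC of a known α-function matches adaptive quadrature to 0.1%."""
        tau, amp, basal = 40.0, 25.0, 3.0
        t = np.arange(0.0, 1501.0, 0.5)
        rel = np.clip(t - 300.0, 0.0, None)
        y = basal + amp * (rel / tau) * np.exp(1 - rel / tau)
        res = auc_above_basal(_make_traj(t, y), stim_onset=300.0)
        oracle, _ = quad(
            lambda s: amp * (s / tau) * np.exp(1 - s / tau), 0.0, 1200.0
        )
        assert res.auc == pytest.approx(oracle, rel=1e-3)
        assert res.time_to_peak == pytest.approx(tau, abs=1.0)

    def test_additive_over_disjoint_windows(self):
        tau, amp = 40.0, 25.0
        t = np.arange(0.0, 1501.0, 0.5)
        rel = np.clip(t - 300.0, 0.0, None)
        y = 3.0 + amp * (rel / tau) * np.exp(1 - rel / tau)
        traj = _make_traj(t, y)
        whole = auc_above_basal(traj, stim_onset=300.0)
        first = auc_above_basal(traj, stim_onset=300.0, window_end=600.0)
        # independent quadrature of the tail with the same baseline
        tail = (t >= 600.0)
        rest = np.trapezoid(np.clip(y[tail] - whole.basal, 0, None), t[tail])
        assert first.auc + rest == pytest.approx(whole.auc, rel=1e-9)

    def test_grid_refinement_invariance(self):
        tau, amp = 40.0, 25.0
        aucs = []
        for dt in (2.0, 0.5, 0.1):
            t = np.arange(0.0, 1501.0, dt)
            rel = np.clip(t - 300.0, 0.0, None)
            y = 3.0 + amp * (rel / tau) * np.exp(1 - rel / tau)
            aucs.append(auc_above_basal(_make_traj(t, y), stim_onset=300.0).auc)
        assert max(aucs) / min(aucs) - 1 < 0.005

    def test_requires_pre_stimulus_window(self):
        t = np.arange(0.0, 500.0)
        with pytest.raises(AnalysisError, match="pre-stimulus"):
            auc_above_basal(_make_traj(t, np.ones_like(t)), stim_onset=100.0)

    def test_time_to_basal_detection(self):
        t = np.arange(0.0, 2001.0)
        y = np.full_like(t, 5.0)
        decay = (t >= 300) & (t < 900)
        y[decay] += 20.0 * np.exp(-(t[decay] - 300.0) / 60.0)
        res = auc_above_basal(_make_traj(t, y), stim_onset=300.0)
        assert res.time_to_basal is not None
        # 5% of basal reached when 20·exp(-x/60) = 0.25 -> x ≈ 263 s
        assert res.time_to_basal == pytest.approx(263.0, abs=10.0)


class TestDoseResponseFits:
    def test_exactly_linear_data(self):
        x = np.repeat([1.0, 4.0, 10.0, 30.0, 100.0], 3)
        y = 5.0 + 2.0 * x
        res = fit_dose_response(x, y)
        assert res.classification == "linear"
        assert res.fit("linear").adjusted_r2 == pytest.approx(1.0)
        assert res.fit("linear").params["slope"] == pytest.approx(2.0)

    def test_noiseless_hill_recovered_to_four_digits(self):
        x = np.repeat([1.0, 2.0, 4.0, 5.0, 6.0, 8.0, 10.0, 30.0, 100.0], 2)
        y = _hill(x, 100.0, 6.7, 2.5)
        fit = fit_dose_response(x, y).fit("hill")
        assert fit.params["max"] == pytest.approx(100.0, rel=1e-4)
        assert fit.params["half_point"] == pytest.approx(6.7, rel=1e-4)
        assert fit.params["n"] == pytest.approx(2.5, rel=1e-4)

    def test_sigmoid_data_classified_non_linear(self):
        rng = np.random.default_rng(0)
        x = np.repeat([1.0, 2.0, 4.0, 6.0, 10.0, 30.0, 100.0], 5)
        y = _hill(x, 100.0, 6.0, 3.0) * (1 + 0.02 * rng.standard_normal(x.size))
        res = fit_dose_response(x, y)
        assert res.fit("linear").adjusted_r2 < 0.9
        assert res.classification == "non-linear"
        assert res.fit("hill").aic < res.fit("linear").aic

    def test_linear_r2_short_circuits_aic(self):
        """Rule fidelity: adjusted R² ≥ 0.9 for the line wins even when the
        Hill fit has lower AIC (it nests the saturating shape)."""
        rng = np.random.default_rng(1)
        x = np.repeat([1.0, 4.0, 10.0, 30.0, 100.0], 5)
        y = (5.0 + 2.0 * x) * (1 + 0.01 * rng.standard_normal(x.size))
        res = fit_dose_response(x, y)
        assert res.fit("linear").adjusted_r2 >= 0.9
        assert res.classification == "linear"

    def test_needs_four_distinct_x(self):
        with pytest.raises(AnalysisError, match="4 distinct"):
            fit_dose_response([1, 1, 2, 3], [1, 2, 3, 4])


class TestSummationAncova:
    def test_identical_groups_verdict_linear(self):
        """Combination made of the very same draws as the summation: the
        type effect is exactly zero and the verdict is linear."""
        rng = np.random.default_rng(0)
        x = np.repeat([1.0, 4.0, 10.0, 30.0, 100.0], 5)
        y = 50.0 + 2.0 * x + rng.standard_normal(x.size)
        res = summation_test(y, y, x)
        assert res.p_type > 0.9
        assert res.type_effect == pytest.approx(0.0, abs=1e-9)
        assert res.verdict == "linear"

    @pytest.mark.parametrize("offset,verdict", [
        (-40.0, "sublinear"), (40.0, "supralinear"),
    ])
    def test_planted_offsets_detected(self, offset, verdict):
        rng = np.random.default_rng(2)
        x = np.repeat([1.0, 4.0, 10.0, 30.0, 100.0], 5)
        mu = 50.0 + 2.0 * x
        sums = mu + 2.0 * rng.standard_normal(x.size)
        combo = mu + offset + 2.0 * rng.standard_normal(x.size)
        res = summation_test(combo, sums, x)
        assert res.p_type < 0.05
        assert res.verdict == verdict
        assert np.sign(res.type_effect) == np.sign(offset)

    def test_unequal_counts_rejected(self):
        x = np.array([1.0, 1.0, 4.0])
        with pytest.raises(AnalysisError, match="unequal"):
            summation_test([1, 2, 3], [1, 2, 3], x)


class TestContributionsAndSensitivity:
    def test_single_pathway_equal_to_all(self):
        out = pathway_contribution({"a": 10.0, "b": 0.0}, 10.0)
        assert out == {"a": 100.0, "b": 0.0}

    def test_no_renormalisation(self):
        out = pathway_contribution({"a": 60.0, "b": 60.0}, 100.0)
        assert out == {"a": 60.0, "b": 60.0}
        assert sum(out.values()) == 120.0

    def test_zero_total_rejected(self):
        with pytest.raises(AnalysisError):
            pathway_contribution({"a": 1.0}, 0.0)

    def test_sensitivity_arithmetic(self):
        res = temporal_sensitivity({3: 10, 20: 12, 40: 15, 80: 30, 300: 28})
        assert res.sensitivity == 20
        assert res.best_iti == 80
        assert res.mean == pytest.approx(19.0)

    def test_constant_profile_zero_sensitivity(self):
        res = temporal_sensitivity({i: 7.0 for i in (3, 20, 40, 80, 300)})
        assert res.sensitivity == 0.0

    def test_ties_resolve_to_larger_interval(self):
        res = temporal_sensitivity({3: 5, 20: 9, 40: 9, 80: 9, 300: 9})
        assert res.best_iti == 300

    def test_missing_interval_rejected(self):
        with pytest.raises(AnalysisError, match="missing"):
            temporal_sensitivity({3: 1, 20: 2, 40: 3, 80: 4})


class TestForestImportance:
    def test_planted_dependence_dominates(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.uniform(-0.1, 0.1, (100, 8)),
                         columns=[f"m{i}" for i in range(8)])
        y = 2.0 * X["m5"].to_numpy() + 0.01 * rng.standard_normal(100)
        res = robustness_importance(X, y, seed=0)
        assert res.ranking[0] == "m5"
        assert res.weight("m5") > 0.5
        assert all(res.weight(f"m{i}") < 0.1 for i in range(8) if i != 5)

    def test_weights_normalised(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(-0.1, 0.1, (40, 5))
        y = X @ rng.standard_normal(5)
        res = robustness_importance(X, y, seed=1)
        assert res.weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(res.weights >= 0)

    def test_constant_response_rejected(self):
        X = np.zeros((40, 3)) + np.arange(3)
        with pytest.raises(AnalysisError, match="constant"):
            robustness_importance(X, np.ones(40), seed=0)

    def test_too_few_rows_rejected(self):
        with pytest.raises(AnalysisError, match=">= 30"):
            robustness_importance(np.zeros((10, 3)), np.arange(10.0), seed=0)
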