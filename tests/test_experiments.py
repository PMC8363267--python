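"""Experiment suites on the fixture network (deterministic oracle runs,
with stochastic spot checks)."""

import numpy as np
import pytest

from synerk import (
    ExperimentError,
    ExperimentPlan,
    KnockoutConfig,
    SolverConfig,
    auc_above_basal,
    build_fixture_network,
    load_timeseries_protocol,
    run,
    run_combination_suite,
    run_lltp_scan,
    run_robustness_suite,
    run_single_pathway_scan,
    run_validation_suite,
)
from synerk.experiments import FIXTURE_PATHWAYS, _merge_ko
from synerk.synthetic import generate_iso_like_inputs

ODE_PLAN = dict(method="ode", post_window=600.0)


@pytest.fixture(scope="module")
def net():
    return build_fixture_network()


class TestValidationSuite:
    def test_refuses_fixture_by_default(self, net):
        with pytest.raises(ExperimentError, match="published"):
            run_validation_suite(net)

    def test_runs_qualitatively_when_allowed(self, net):
        plan = ExperimentPlan(name="val", method="ode", post_window=1800.0)
        res = run_validation_suite(net, plan, allow_fixture=True)
        t = res.table.set_index("protocol")
        # GTPase transient responds to the uncaging-style calcium plateau
        assert t.loc["rasgtp_uncaging", "auc"] > 0
        # the strong tetanisation drives ppERK well above basal, with a
        # peak following the stimulation (not instantaneous)
        row = t.loc["llp_2x100Hz"]
        assert row["peak"] > 1.5 * row["basal"]
        assert row["time_to_peak"] > 0


class TestSinglePathwayScans:
    def test_camp_duration_scan_is_linear(self, net):
        res = run_single_pathway_scan(
            net, "cAMP", [1, 4, 10, 30, 100], "duration", 500.0,
            plan=ExperimentPlan(name="camp", **ODE_PLAN),
        )
        assert res.dose_fit.classification == "linear"

    def test_calcium_duration_scan_is_ultrasensitive(self, net):
        res = run_single_pathway_scan(
            net, "calcium", [1, 2, 4, 5, 6, 8, 10, 30, 100], "duration", 500.0,
            plan=ExperimentPlan(name="ca", **ODE_PLAN),
        )
        assert res.dose_fit.classification == "non-linear"
        hill = res.dose_fit.fit("hill")
        assert hill.converged and hill.params["n"] > 2.0

    def test_blocking_switch_removes_ultrasensitivity(self, net):
        """Zeroing autophosphorylation leaves only the graded calcium arm."""
        ko = KnockoutConfig(zeroed_rate_labels={"ck_auto", "ck_act"})
        ctrl = run_single_pathway_scan(
            net, "calcium", [1, 2, 4, 6, 10, 30, 100], "duration", 500.0,
            plan=ExperimentPlan(name="ctrl", **ODE_PLAN),
        )
        blocked = run_single_pathway_scan(
            net, "calcium", [1, 2, 4, 6, 10, 30, 100], "duration", 500.0,
            ko=ko, plan=ExperimentPlan(name="ko", **ODE_PLAN),
        )
        long_ctrl = ctrl.table.query("x == 100")["auc"].mean()
        long_ko = blocked.table.query("x == 100")["auc"].mean()
        assert long_ko < 0.5 * long_ctrl
        n_ctrl = ctrl.dose_fit.fit("hill").params["n"]
        n_ko = blocked.dose_fit.fit("hill").params["n"]
        assert n_ko < n_ctrl

    def test_stochastic_trials_give_per_seed_rows(self, net):
        plan = ExperimentPlan(
            name="stoch", method="tau_leap_adaptive", post_window=200.0,
            seeds=(1, 2, 3, 4, 5),
        )
        res = run_single_pathway_scan(net, "cAMP", [1, 4, 10, 30], "duration",
                                      500.0, plan=plan)
        assert len(res.table) == 4 * 5
        spread = res.table.groupby("x")["auc"].std()
        assert (spread > 0).all()


class TestCombinationSuite:
    def test_competing_branches_sum_sublinearly(self, net):
        res = run_combination_suite(
            net, {"cAMP": 500.0, "Gbg": 100.0}, [1, 4, 10, 30, 100],
            "duration", plan=ExperimentPlan(name="combo", **ODE_PLAN),
        )
        assert (res.table["auc_combo"] < res.table["auc_sum"]).all()
        assert res.ancova.verdict == "sublinear"
        assert res.ancova.p_stim < 0.05

    def test_needs_two_inputs(self, net):
        with pytest.raises(ExperimentError, match="two inputs"):
            run_combination_suite(net, {"cAMP": 500.0}, [1, 4, 10, 30])


class TestLltpScans:
    def test_camp_favors_spaced_auc_but_massed_peak(self, net):
        res = run_lltp_scan(net, {"cAMP": 500.0},
                            plan=ExperimentPlan(name="camp_lltp", method="ode",
                                                post_window=900.0))
        by_iti = res.table.set_index("iti")
        assert by_iti.loc[300, "auc"] > by_iti.loc[3, "auc"]
        assert by_iti.loc[300, "peak"] < by_iti.loc[20, "peak"]
        assert res.sensitivity.best_iti in (80.0, 300.0)

    def test_calcium_switch_fires_only_for_massed(self, net):
        res = run_lltp_scan(net, {"calcium": 1000.0},
                            plan=ExperimentPlan(name="ca_lltp", method="ode",
                                                post_window=900.0))
        by_iti = res.table.set_index("iti")
        massed = by_iti.loc[[3, 20, 40], "peak_switch"]
        spaced = by_iti.loc[[80, 300], "peak_switch"]
        assert massed.min() > 2 * spaced.max()
        # peak switch activity is highest for the shortest interval
        assert by_iti["peak_switch"].idxmax() == 3

    def test_pathway_contributions_reported_without_renormalising(self, net):
        res = run_lltp_scan(
            net, {"calcium": 1000.0, "cAMP": 500.0}, iti_set=[3, 300],
            pathway_knockouts={k: FIXTURE_PATHWAYS[k] for k in ("camp_gef", "switch")},
            plan=ExperimentPlan(name="contrib", method="ode", post_window=600.0),
        )
        assert set(res.contributions) == {"camp_gef", "switch"}
        for per_iti in res.contributions.values():
            assert all(v >= 0 for v in per_iti.values())


class TestRobustnessSuite:
    def test_control_row_is_reference(self, net):
        res = run_robustness_suite(
            net, {"calcium": 1000.0, "cAMP": 500.0}, mode="single", delta=0.1,
            plan=ExperimentPlan(name="rob", method="ode", post_window=600.0),
        )
        t = res.table
        assert t.iloc[0]["pct_change_mean"] == 0.0
        assert t.iloc[0]["pct_change_sensitivity"] == 0.0
        # one +10% and one -10% row per perturbed species, plus control
        n_species = len(res.provenance["perturbed"])
        assert len(t) == 1 + 2 * n_species

    def test_merge_knockouts_unions_fields(self):
        a = KnockoutConfig(zeroed_rate_labels={"x"}, quantity_multipliers={"A": 2.0})
        b = KnockoutConfig(zeroed_rate_labels={"y"}, dimerization_enabled=False)
        m = _merge_ko(a, b)
        assert m.zeroed_rate_labels == {"x", "y"}
        assert m.quantity_multipliers == {"A": 2.0}
        assert not m.dimerization_enabled


class TestIsoConditions:
    def test_combined_conditions_exceed_singles(self, net):
        """LTP-producing combinations out-activate any single condition."""
        from synerk import equilibrated_network

        frames = generate_iso_like_inputs(seed=0, dt=2.0)
        eq = equilibrated_network(net)
        aucs = {}
        for cond, df in frames.items():
            proto = load_timeseries_protocol(df, name=cond).shifted(300.0)
            tr = run(eq, proto, SolverConfig(method="ode", t_end=300.0 + 900.0 + 600.0,
                                             output_interval=2.0))
            aucs[cond] = auc_above_basal(tr, "ppERK", 300.0).auc
        singles = max(aucs["ISO"], aucs["100Hz"], aucs["5Hz"])
        assert aucs["ISO+100Hz"] > singles
        assert aucs["ISO+5Hz"] > singles
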