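"""Propagators: unit conversions, determinism, conservation, steady state."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import fsolve

from synerk import (
    SimulationError,
    SolverConfig,
    build_fixture_network,
    concentration_to_count,
    count_factor,
    count_to_concentration,
    load_trajectories,
    run,
    run_to_steady_state,
    run_trials,
    save_trajectories,
)
from synerk.simulate import _compile, _ode_rhs
from synerk.stimuli import single_pulse_protocol

from conftest import moiety_totals


class TestUnitsBridge:
    @pytest.mark.parametrize("conc,vol,expected", [
        (0.0, 4.0, 0),
        (1.0, 4.0, 2),     # 1e-9 · N_A · 4e-15 ≈ 2.409
        (50.0, 4.0, 120),  # 50 · 2.409 ≈ 120.4
        (100.0, 1000.0, 60221),
    ])
    def test_round_to_molecules(self, conc, vol, expected):
        assert concentration_to_count(conc, vol) == expected

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            concentration_to_count(-1.0, 4.0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(conc=st.floats(0.0, 1e4), vol=st.sampled_from([0.1, 0.5, 4.0, 1000.0]))
    def test_inverse_within_half_count(self, conc, vol):
        n = concentration_to_count(conc, vol)
        back = count_to_concentration(n, vol)
        assert abs(back - conc) * count_factor(vol) <= 0.5 + 1e-9


class TestDeterminismAndTrials:
    @pytest.mark.parametrize("method", ["ssa_exact", "tau_leap_adaptive"])
    def test_same_seed_bit_identical(self, eq_net, method):
        proto = single_pulse_protocol("calcium", 500.0, 5.0, onset=2.0)
        cfg = SolverConfig(method=method, t_end=30.0, seed=42)
        a = run(eq_net, proto, cfg)
        b = run(eq_net, proto, cfg)
        assert np.array_equal(a.amounts, b.amounts)

    def test_trials_are_distinct_and_reproducible(self, eq_net):
        cfg = SolverConfig(method="tau_leap_adaptive", t_end=20.0)
        proto = single_pulse_protocol("cAMP", 500.0, 5.0)
        first = run_trials(eq_net, proto, cfg, seeds=[1, 2, 3, 4, 5])
        again = run_trials(eq_net, proto, cfg, seeds=[1, 2, 3, 4, 5])
        assert len(first) == 5
        for a, b in zip(first, again):
            assert np.array_equal(a.amounts, b.amounts)
        assert any(
            not np.array_equal(first[0].amounts, t.amounts) for t in first[1:]
        )

    def test_duplicate_seeds_rejected(self, eq_net):
        with pytest.raises(ValueError, match="duplicate"):
            run_trials(eq_net, None, SolverConfig(t_end=5.0), seeds=[1, 1, 2])


class TestConservationAndPositivity:
    @pytest.mark.parametrize("method", ["ssa_exact", "tau_leap_adaptive"])
    def test_moieties_exactly_constant_stochastic(
        self, eq_net, fixture_moieties, method
    ):
        proto = single_pulse_protocol("calcium", 2000.0, 2.0, onset=2.0)
        traj = run(eq_net, proto, SolverConfig(method=method, t_end=60.0, seed=7))
        for total in moiety_totals(traj, fixture_moieties):
            assert total.min() == total.max()

    def test_counts_never_negative(self, eq_net):
        proto = single_pulse_protocol("calcium", 5000.0, 5.0)
        traj = run(eq_net, proto,
                   SolverConfig(method="tau_leap_adaptive", t_end=120.0, seed=3))
        assert traj.amounts.min() >= 0

    def test_unstimulated_control_stays_at_basal(self, eq_net):
        """No stimulus: free calcium stays within 3 SE of its resting mean."""
        traj = run(eq_net, None,
                   SolverConfig(method="ssa_exact", t_end=300.0, seed=11))
        ca = traj.series("Ca")
        resting = eq_net.initial_concentrations()[eq_net.species_index("Ca")]
        se = ca.std(ddof=1) / np.sqrt(_effective_n(ca))
        assert abs(ca.mean() - resting) < 3 * max(se, 1e-9)


def _effective_n(x):
    """Crude effective sample size correcting lag-1 autocorrelation."""
    x = np.asarray(x, float)
    r = np.corrcoef(x[:-1], x[1:])[0, 1]
    r = min(max(r, 0.0), 0.999)
    return x.size * (1 - r) / (1 + r)


class TestLargeVolumeLimit:
    def test_tau_leap_matches_ssa_mean(self, eq_net_v1000, camp_pulse_v1000):
        """Accelerated and exact propagators agree distributionally."""
        proto, _ode, ssa = camp_pulse_v1000
        tau = [
            run(eq_net_v1000, proto,
                SolverConfig(method="tau_leap_adaptive", t_end=80.0, seed=s))
            for s in range(1, 51)
        ]
        end_ssa = np.array([t.concentrations[-1] for t in ssa])
        end_tau = np.array([t.concentrations[-1] for t in tau])
        se = np.sqrt(end_ssa.var(0, ddof=1) / 50 + end_tau.var(0, ddof=1) / 50)
        diff = np.abs(end_ssa.mean(0) - end_tau.mean(0))
        # floor the SE at one molecule to keep zero-variance species meaningful
        floor = 1.0 / count_factor(eq_net_v1000.compartment_volume)
        assert np.all(diff < 3 * np.maximum(se, floor))


class TestSteadyState:
    def test_fixture_relaxes_to_analytic_fixed_point(self, fixture_net):
        """ODE relaxation lands on the constrained root-finding fixed point.

        The mass-action fixed point is only unique within a stoichiometric
        compatibility class, so the oracle replaces one rate equation per
        conserved moiety with the corresponding conservation constraint.
        """
        comp = _compile(fixture_net)
        rhs = _ode_rhs(comp, np.zeros(len(fixture_net.species), bool))
        y0 = fixture_net.initial_concentrations()
        moieties = fixture_net.conserved_moieties()
        idx = {n: i for i, n in enumerate(fixture_net.species_names)}
        constrained = []  # (replaced species row, coefficient vector, total)
        used_rows: set[int] = set()
        for m in moieties:
            coeff = np.zeros(len(y0))
            for name, c in m.items():
                coeff[idx[name]] = c
            row = next(idx[n] for n in m if idx[n] not in used_rows)
            used_rows.add(row)
            constrained.append((row, coeff, float(coeff @ y0)))

        def objective(y):
            out = rhs(0.0, y).copy()
            for row, coeff, total in constrained:
                out[row] = coeff @ y - total
            return out

        root = fsolve(objective, y0, full_output=False)
        ss = run_to_steady_state(fixture_net)
        j = fixture_net.species_index("ppERK")
        assert root[j] > 1.0  # a meaningful basal pool, not a degenerate root
        assert ss.concentrations[j] == pytest.approx(root[j], rel=0.05)

    def test_basal_calcium_and_camp_levels(self, fixture_net):
        """Resting levels mirror the modelled basal second messengers
        (~50 nM free calcium, ~30 nM cAMP)."""
        ss = run_to_steady_state(fixture_net)
        basal = ss.as_dict()
        assert basal["Ca"] == pytest.approx(50.0, rel=0.02)
        assert basal["cAMP"] == pytest.approx(30.0, rel=0.02)

    def test_drift_criterion_enforced(self, fixture_net):
        """Too-short relaxation from a cold start reports the drifting species."""
        with pytest.raises(SimulationError, match="drifts"):
            run_to_steady_state(fixture_net, t_max=240.0, window=120.0)


class TestTrajectoryStore:
    def test_hdf5_round_trip(self, eq_net, tmp_path):
        cfg = SolverConfig(method="tau_leap_adaptive", t_end=10.0)
        trs = run_trials(eq_net, single_pulse_protocol("cAMP", 200.0, 2.0),
                         cfg, seeds=[1, 2])
        path = tmp_path / "trajs.h5"
        save_trajectories(path, trs)
        back = load_trajectories(path)
        assert len(back) == 2
        for a, b in zip(trs, back):
            assert np.array_equal(a.amounts, b.amounts)
            assert a.species_names == b.species_names
            assert a.seed == b.seed

    def test_csv_export_has_all_species(self, eq_net, tmp_path):
        traj = run(eq_net, None, SolverConfig(method="ode", t_end=5.0))
        df = traj.to_frame()
        assert set(eq_net.species_names) <= set(df.columns)
        assert df["time_s"].is_monotonic_increasing
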