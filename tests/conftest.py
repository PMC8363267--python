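import numpy as np
import pytest

from synerk import (
    SolverConfig,
    build_fixture_network,
    equilibrated_network,
    run,
    single_pulse_protocol,
)


@pytest.fixture(scope="session")
def fixture_net():
    return build_fixture_network()


@pytest.fixture(scope="session")
def eq_net(fixture_net):
    """Fixture network relaxed to its resting state (deterministic)."""
    return equilibrated_network(fixture_net)


@pytest.fixture(scope="session")
def eq_net_v1000():
    """Large-volume fixture (mass-action limit) at rest."""
    return equilibrated_network(build_fixture_network(volume=1000.0))


@pytest.fixture(scope="session")
def camp_pulse_v1000(eq_net_v1000):
    """Shared large-volume comparison runs: 50 SSA seeds + ODE reference.

    The protocol drives the linear cAMP branch (10 s at 0.5 µM) — away from
    the kinase switch's threshold, where the mean-field limit is the honest
    reference for the stochastic mean.
    """
    proto = single_pulse_protocol("cAMP", 500.0, 10.0, onset=5.0)
    ode = run(eq_net_v1000, proto, SolverConfig(method="ode", t_end=80.0))
    ssa = [
        run(eq_net_v1000, proto,
            SolverConfig(method="ssa_exact", t_end=80.0, seed=s))
        for s in range(1, 51)
    ]
    return proto, ode, ssa


@pytest.fixture(scope="session")
def fixture_moieties(fixture_net):
    """Conserved totals from the stoichiometric left null space (exact)."""
    return fixture_net.conserved_moieties()


def moiety_totals(traj, moieties):
    """Per-time totals for each conserved moiety, in counts."""
    idx = {n: i for i, n in enumerate(traj.species_names)}
    out = []
    for m in moieties:
        coeffs = np.zeros(len(traj.species_names))
        for name, c in m.items():
            coeffs[idx[name]] = c
        out.append(traj.amounts @ coeffs)
    return out
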