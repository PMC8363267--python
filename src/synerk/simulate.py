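"""Propagators: exact SSA, adaptive tau-leaping and a deterministic ODE oracle.

All three methods consume the same :class:`~synerk.network.ReactionNetwork`
and :class:`~synerk.stimuli.Protocol` and emit a :class:`Trajectory` sampled
on a uniform output grid.  Stochastic methods are bit-reproducible for a
given seed.  Counts and concentrations are linked through the compartment
volume: n = c · N_A · V (with c in nM and V in µm³, one nM in 4 µm³ is
about 2.4 molecules), so small spine-sized volumes are intrinsically noisy
and a large volume recovers the mass-action ODE limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import _engine
from .network import ReactionNetwork
from .stimuli import EMPTY_PROTOCOL, Protocol, resolve_input_species

AVOGADRO = 6.02214076e23
#: molecules per nM per µm³  (1e-9 mol/L · N_A · 1e-15 L/µm³)
COUNTS_PER_NM_UM3 = 1e-9 * AVOGADRO * 1e-15


class SimulationError(RuntimeError):
    pass


def count_factor(volume: float) -> float:
    """Molecules per nM for a compartment of ``volume`` µm³."""
    return COUNTS_PER_NM_UM3 * volume


def concentration_to_count(conc, volume: float):
    """Round a concentration (nM) to whole molecules in ``volume`` µm³."""
    conc = np.asarray(conc, float)
    if np.any(conc < 0) or volume < 0:
        raise ValueError("concentration and volume must be >= 0")
    out = np.rint(conc * count_factor(volume)).astype(np.int64)
    return out if out.ndim else int(out)


def count_to_concentration(count, volume: float):
    """Molecule count back to nM; inverse of :func:`concentration_to_count`
    within half a count."""
    count = np.asarray(count, float)
    if np.any(count < 0) or volume <= 0:
        raise ValueError("count must be >= 0 and volume > 0")
    out = count / count_factor(volume)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class SolverConfig:
    method: str = "tau_leap_adaptive"  # ssa_exact | tau_leap_adaptive | ode
    t_end: float = 100.0
    leap_tolerance: float = 0.1
    seed: int = 0
    output_interval: float = 1.0
    ode_rtol: float = 1e-8

    def __post_init__(self) -> None:
        if self.method not in ("ssa_exact", "tau_leap_adaptive", "ode"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.leap_tolerance <= 0:
            raise ValueError("leap_tolerance must be > 0")
        if self.output_interval <= 0:
            raise ValueError("output_interval must be > 0")
        if self.t_end <= 0:
            raise ValueError("t_end must be > 0")


@dataclass(frozen=True)
class Trajectory:
    """Time-stamped species amounts from one trial.

    ``amounts`` are molecule counts (integers for stochastic methods,
    continuous for the ODE); ``concentrations`` derives nM through the
    compartment volume.
    """

    times: np.ndarray            # (T,), uniformly spaced
    amounts: np.ndarray          # (T, S)
    species_names: tuple[str, ...]
    volume: float                # µm³
    method: str
    seed: int | None = None
    metadata: Mapping[str, object] = field(default_factory=dict)

    @property
    def concentrations(self) -> np.ndarray:
        return self.amounts / count_factor(self.volume)

    def series(self, species: str, kind: str = "concentration") -> np.ndarray:
        j = self.species_names.index(species)
        if kind == "concentration":
            return self.concentrations[:, j]
        return self.amounts[:, j]

    def final_concentrations(self) -> dict[str, float]:
        conc = self.concentrations[-1]
        return dict(zip(self.species_names, conc.tolist()))

    def to_frame(self) -> pd.DataFrame:
        """Wide table: time_s plus one nM column per species."""
        df = pd.DataFrame(self.concentrations, columns=list(self.species_names))
        df.insert(0, "time_s", self.times)
        return df


@dataclass(frozen=True)
class SteadyState:
    amounts: np.ndarray          # mean counts over the final window
    concentrations: np.ndarray   # nM
    species_names: tuple[str, ...]
    drift: float                 # max relative change between assessment windows
    worst_species: str

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.species_names, self.concentrations.tolist()))


# ---------------------------------------------------------------------------
# network compilation


@dataclass(frozen=True)
class _Compiled:
    r1: np.ndarray      # (n_dir,) first reactant index or -1
    r2: np.ndarray      # (n_dir,) second reactant index or -1
    dbl: np.ndarray     # (n_dir,) homodimeric flag
    stoich: np.ndarray  # (n_dir, S) net integer change
    k_conc: np.ndarray  # (n_dir,) rate constant in concentration units
    labels: tuple[str, ...]


def _compile(net: ReactionNetwork) -> _Compiled:
    idx = {n: i for i, n in enumerate(net.species_names)}
    r1, r2, dbl, k, labels, rows = [], [], [], [], [], []
    S = len(net.species)

    def add(reactants, products, rate, label):
        col = np.zeros(S, np.int64)
        for nm in reactants:
            col[idx[nm]] -= 1
        for nm in products:
            col[idx[nm]] += 1
        ii = [idx[nm] for nm in reactants]
        r1.append(ii[0] if ii else -1)
        r2.append(ii[1] if len(ii) > 1 else -1)
        dbl.append(len(ii) == 2 and ii[0] == ii[1])
        k.append(rate)
        labels.append(label)
        rows.append(col)

    for rx in net.reactions:
        add(rx.reactants, rx.products, rx.kf, rx.label)
        if rx.reversible:
            add(rx.products, rx.reactants, rx.kr, rx.label + "_rev")
    return _Compiled(
        r1=np.asarray(r1, np.int64),
        r2=np.asarray(r2, np.int64),
        dbl=np.asarray(dbl, np.bool_),
        stoich=np.stack(rows).astype(np.int64),
        k_conc=np.asarray(k, float),
        labels=tuple(labels),
    )


def _stochastic_rate_constants(comp: _Compiled, volume: float) -> np.ndarray:
    """Concentration-space constants -> count-space propensity constants."""
    f = count_factor(volume)
    c = comp.k_conc.copy()
    zeroth = comp.r1 < 0
    bimol = comp.r2 >= 0
    c[zeroth] *= f            # nM/s -> molecules/s
    c[bimol] /= f             # /nM/s -> per-pair /s
    c[comp.dbl] *= 2.0        # deterministic k[A]^2 vs n(n-1)/2 combinatorics
    return c


def _ode_rhs(comp: _Compiled, clamped: np.ndarray):
    r1, r2, dbl, k, stoich = comp.r1, comp.r2, comp.dbl, comp.k_conc, comp.stoich
    uni = (r1 >= 0) & (r2 < 0)
    bi = r2 >= 0

    def rhs(_t, y):
        v = k.copy()
        v[uni] *= y[r1[uni]]
        v[bi] *= y[r1[bi]] * y[r2[bi]]
        dy = stoich.T @ v
        dy[clamped] = 0.0
        return dy

    return rhs


# ---------------------------------------------------------------------------
# running


def _resolve_clamp_plan(net: ReactionNetwork, protocol: Protocol, t_end: float):
    """Clamp segments with canonical input names mapped to species indices."""
    plan = []
    for t0, t1, clamp in protocol.clamp_segments(t_end):
        resolved = {}
        for canon, value in clamp.items():
            sp = resolve_input_species(net, canon)
            resolved[net.species_index(sp)] = value
        plan.append((t0, t1, resolved))
    return plan


def run(
    net: ReactionNetwork,
    protocol: Protocol | None = None,
    cfg: SolverConfig = SolverConfig(),
    initial_concentrations: np.ndarray | None = None,
) -> Trajectory:
    """Propagate ``net`` under ``protocol`` and sample on a uniform grid.

    ``initial_concentrations`` (nM, ordered as the network's species)
    overrides the network's declared initial state — pass an equilibrated
    state here to start from rest.
    """
    protocol = protocol or EMPTY_PROTOCOL
    comp = _compile(net)
    if np.any(comp.k_conc < 0):
        bad = comp.labels[int(np.argmin(comp.k_conc))]
        raise SimulationError(f"negative rate constant in reaction {bad!r}")
    y0 = (
        net.initial_concentrations()
        if initial_concentrations is None
        else np.asarray(initial_concentrations, float)
    )
    if y0.shape != (len(net.species),):
        raise ValueError("initial_concentrations has wrong length")
    grid = np.round(
        np.arange(0.0, cfg.t_end + 0.5 * cfg.output_interval, cfg.output_interval), 9
    )
    plan = _resolve_clamp_plan(net, protocol, cfg.t_end)
    meta = {"protocol": protocol.name, "network": net.metadata.get("name", "")}
    if cfg.method == "ode":
        amounts = _run_ode(net, comp, y0, plan, grid, cfg)
        return Trajectory(grid, amounts, net.species_names, net.compartment_volume,
                          "ode", None, meta)
    amounts = _run_stochastic(net, comp, y0, plan, grid, cfg)
    return Trajectory(grid, amounts, net.species_names, net.compartment_volume,
                      cfg.method, cfg.seed, meta)


def _run_ode(net, comp, y0, plan, grid, cfg) -> np.ndarray:
    S = len(net.species)
    out = np.empty((grid.size, S))
    y = y0.copy()
    gpos = 0
    for t0, t1, clamp in plan:
        clamped = np.zeros(S, bool)
        for j, v in clamp.items():
            clamped[j] = True
            y[j] = v
        take = (grid >= t0 - 1e-9) & (grid < t1 - 1e-9)
        t_eval = grid[take]
        # always integrate through t1 so the carried state is the segment end
        sol = solve_ivp(
            _ode_rhs(comp, clamped), (t0, t1), y, method="LSODA",
            t_eval=np.append(t_eval, t1),
            rtol=cfg.ode_rtol, atol=1e-10,
        )
        if not sol.success:
            raise SimulationError(f"ODE solver failed on [{t0}, {t1}]: {sol.message}")
        if t_eval.size:
            out[gpos:gpos + t_eval.size] = sol.y.T[: t_eval.size]
            gpos += t_eval.size
        y = sol.y[:, -1].copy()
        y[y < 0] = 0.0  # solver tolerance can leave tiny negatives
    while gpos < grid.size:
        out[gpos] = y
        gpos += 1
    np.clip(out, 0.0, None, out=out)  # solver round-off can dip below zero
    return out * count_factor(net.compartment_volume)


def _run_stochastic(net, comp, y0, plan, grid, cfg) -> np.ndarray:
    S = len(net.species)
    vol = net.compartment_volume
    n = concentration_to_count(y0, vol)
    n = np.asarray(n, np.int64).copy()
    c = _stochastic_rate_constants(comp, vol)
    out = np.zeros((grid.size, S), np.int64)
    _engine.seed_rng(int(cfg.seed))
    gpos = 0
    kernel = _engine.ssa_segment if cfg.method == "ssa_exact" else _engine.tau_segment
    for t0, t1, clamp in plan:
        clamp_idx = np.asarray(sorted(clamp), np.int64)
        clamp_val = np.asarray(
            [concentration_to_count(clamp[j], vol) for j in clamp_idx], np.int64
        )
        args = (n, t0, t1, c, comp.r1, comp.r2, comp.dbl, comp.stoich,
                clamp_idx, clamp_val, grid, gpos, out)
        if cfg.method == "ssa_exact":
            _, gpos = kernel(*args)
        else:
            _, gpos = kernel(*args, cfg.leap_tolerance)
    while gpos < grid.size:
        out[gpos] = n
        gpos += 1
    if np.any(out < 0):
        raise SimulationError("negative species count recorded")
    return out


def run_trials(
    net: ReactionNetwork,
    protocol: Protocol | None,
    cfg: SolverConfig,
    seeds: Sequence[int],
    initial_concentrations: np.ndarray | None = None,
) -> list[Trajectory]:
    """Repeat one stochastic condition across ``seeds`` (default design: 5)."""
    seeds = list(seeds)
    if len(set(seeds)) != len(seeds):
        raise ValueError(f"duplicate seeds: {seeds}")
    if cfg.method == "ode":
        raise ValueError("run_trials is for stochastic methods; the ODE has no seed")
    return [
        run(net, protocol, SolverConfig(
            method=cfg.method, t_end=cfg.t_end, leap_tolerance=cfg.leap_tolerance,
            seed=int(s), output_interval=cfg.output_interval, ode_rtol=cfg.ode_rtol,
        ), initial_concentrations)
        for s in seeds
    ]


def run_to_steady_state(
    net: ReactionNetwork,
    cfg: SolverConfig | None = None,
    t_max: float = 5400.0,
    window: float = 600.0,
    drift_tol: float = 0.01,
) -> SteadyState:
    """Relax the unstimulated network and assess residual drift.

    Simulates ``t_max`` seconds (>= 3600 by default, mirroring the roughly
    one-hour equilibration the full model uses), then compares per-species
    means over the last two ``window``-second stretches; the maximum
    relative change must fall below ``drift_tol``.
    """
    if t_max < 2 * window:
        raise ValueError("t_max must cover two assessment windows")
    cfg = cfg or SolverConfig(method="ode")
    base = SolverConfig(
        method=cfg.method, t_end=t_max, leap_tolerance=cfg.leap_tolerance,
        seed=cfg.seed, output_interval=min(cfg.output_interval * 10, window / 20),
        ode_rtol=cfg.ode_rtol,
    )
    traj = run(net, EMPTY_PROTOCOL, base)
    w2 = traj.times >= t_max - window
    w1 = (traj.times >= t_max - 2 * window) & ~w2
    m1 = traj.amounts[w1].mean(axis=0)
    m2 = traj.amounts[w2].mean(axis=0)
    scale = np.maximum(np.maximum(m1, m2), 1.0)  # ignore sub-molecule species
    rel = np.abs(m2 - m1) / scale
    worst = int(np.argmax(rel))
    drift = float(rel[worst])
    if drift >= drift_tol:
        raise SimulationError(
            f"steady state not reached at t={t_max} s: species "
            f"{net.species_names[worst]!r} drifts {drift:.3%} per {window:g} s window"
        )
    return SteadyState(
        amounts=m2,
        concentrations=m2 / count_factor(net.compartment_volume),
        species_names=net.species_names,
        drift=drift,
        worst_species=net.species_names[worst],
    )


def equilibrated_network(net: ReactionNetwork, **kw) -> ReactionNetwork:
    """Copy of ``net`` whose initial concentrations are its resting state."""
    ss = run_to_steady_state(net, **kw)
    out = net
    for name, conc in ss.as_dict().items():
        out = out.with_species_concentration(name, conc)
    return out


# ---------------------------------------------------------------------------
# trajectory store


def save_trajectories(path: str | Path, trajectories: Sequence[Trajectory]) -> None:
    """HDF5 store: one group per trial with times/amounts datasets."""
    with h5py.File(path, "w") as h5:
        for i, tr in enumerate(trajectories):
            g = h5.create_group(f"trial_{i:03d}")
            g.create_dataset("times", data=tr.times)
            g.create_dataset("amounts", data=tr.amounts)
            g.attrs["species"] = list(tr.species_names)
            g.attrs["volume"] = tr.volume
            g.attrs["method"] = tr.method
            g.attrs["seed"] = -1 if tr.seed is None else tr.seed
            for k, v in tr.metadata.items():
                g.attrs[f"meta_{k}"] = str(v)


def load_trajectories(path: str | Path) -> list[Trajectory]:
    out = []
    with h5py.File(path, "r") as h5:
        for key in sorted(h5):
            g = h5[key]
            seed = int(g.attrs["seed"])
            out.append(Trajectory(
                times=g["times"][:],
                amounts=g["amounts"][:],
                species_names=tuple(str(s) for s in g.attrs["species"]),
                volume=float(g.attrs["volume"]),
                method=str(g.attrs["method"]),
                seed=None if seed < 0 else seed,
                metadata={
                    k[5:]: str(v) for k, v in g.attrs.items() if k.startswith("meta_")
                },
            ))
    return out


def export_csv(path: str | Path, trajectory: Trajectory) -> None:
    trajectory.to_frame().to_csv(path, index=False)
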