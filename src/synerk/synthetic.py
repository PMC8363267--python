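"""Seeded generators for datasets with known ground truth.

Every statistic in :mod:`synerk.analysis` has a matching generator here, so
parameter recovery, null calibration and planted-signal detection can be
tested without running the simulator.  The noise model for pseudo-AUC data
is multiplicative Gaussian (trial spread scales with signal, as it does for
stochastic simulation AUCs).  All outputs are bit-reproducible from the
seed, and the ground truth travels with the dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .stimuli import LLTP_ITIS

#: the calcium duration grid of the single-pathway experiments (s, at 0.5 µM)
CALCIUM_DURATIONS: tuple[float, ...] = (1, 2, 4, 5, 6, 8, 10, 30, 100)
#: single-pulse amplitude grids (nM, 1 s pulses)
CALCIUM_AMPLITUDES: tuple[float, ...] = (200, 300, 500, 1000, 1500, 2000, 5000)
CAMP_AMPLITUDES: tuple[float, ...] = (100, 200, 500, 1000, 1500, 2000)
GBG_AMPLITUDES: tuple[float, ...] = (5, 30, 100, 500)

GENERATORS = (
    "hill_dose_response",
    "linear_dose_response",
    "ancova_groups",
    "iti_profile",
    "forest_planted",
)


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticSpec:
    generator: str
    params: Mapping[str, object] = field(default_factory=dict)
    noise_sd: float = 0.02      # fractional (multiplicative) noise
    n_trials: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.generator not in GENERATORS:
            raise SyntheticError(
                f"unknown generator {self.generator!r}; valid: {GENERATORS}"
            )
        if self.noise_sd < 0:
            raise SyntheticError("noise_sd must be >= 0")


@dataclass(frozen=True)
class SyntheticDataset:
    data: pd.DataFrame | dict
    ground_truth: dict
    spec: SyntheticSpec


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Dispatch to the generator named by ``spec``; seeded and reproducible."""
    rng = np.random.default_rng(spec.seed)
    p = dict(spec.params)
    if spec.generator == "hill_dose_response":
        x = np.asarray(p.get("x_values", CALCIUM_DURATIONS), float)
        top = float(p.get("max", 100.0))
        half = float(p.get("half_point", 6.7))
        n = float(p.get("n", 2.5))
        xx = np.repeat(x, spec.n_trials)
        mu = top * xx ** n / (xx ** n + half ** n)
        y = mu * (1.0 + spec.noise_sd * rng.standard_normal(xx.size))
        return SyntheticDataset(
            pd.DataFrame({"x": xx, "y": y}),
            {"max": top, "half_point": half, "n": n},
            spec,
        )
    if spec.generator == "linear_dose_response":
        x = np.asarray(p.get("x_values", CALCIUM_DURATIONS), float)
        intercept = float(p.get("intercept", 10.0))
        slope = float(p.get("slope", 3.0))
        xx = np.repeat(x, spec.n_trials)
        mu = intercept + slope * xx
        y = mu * (1.0 + spec.noise_sd * rng.standard_normal(xx.size))
        return SyntheticDataset(
            pd.DataFrame({"x": xx, "y": y}),
            {"intercept": intercept, "slope": slope},
            spec,
        )
    if spec.generator == "ancova_groups":
        x = np.asarray(p.get("x_values", (1, 4, 10, 30, 100)), float)
        slope = float(p.get("slope", 2.0))
        base = float(p.get("base", 50.0))
        offset = float(p.get("offset", 0.0))  # combo minus summation
        sd = float(p.get("noise_abs", max(base * spec.noise_sd, 1e-12)))
        xx = np.repeat(x, spec.n_trials)
        mu = base + slope * xx
        sums = mu + sd * rng.standard_normal(xx.size)
        combo = mu + offset + sd * rng.standard_normal(xx.size)
        return SyntheticDataset(
            {"combo": combo, "sum": sums, "x": xx},
            {"offset": offset, "noise_abs": sd},
            spec,
        )
    if spec.generator == "iti_profile":
        means = dict(p.get("means", {i: float(v) for i, v in
                                     zip(LLTP_ITIS, (10, 12, 15, 30, 28))}))
        missing = [i for i in LLTP_ITIS if i not in means]
        if missing:
            raise SyntheticError(f"iti_profile means missing ITIs {missing}")
        vals = np.array([means[i] for i in LLTP_ITIS], float)
        truth_best = max((v, i) for i, v in zip(LLTP_ITIS, vals))[1]
        return SyntheticDataset(
            {"auc_by_iti": {float(i): float(means[i]) for i in LLTP_ITIS}},
            {
                "sensitivity": float(vals.max() - vals.min()),
                "mean": float(vals.mean()),
                "best_iti": float(truth_best),
            },
            spec,
        )
    if spec.generator == "forest_planted":
        n_rows = int(p.get("n_rows", 100))
        n_features = int(p.get("n_features", 10))
        planted = int(p.get("planted_index", 0))
        coef = float(p.get("coef", 1.0))
        sd = float(p.get("noise_abs", 0.01))
        X = rng.uniform(-0.1, 0.1, size=(n_rows, n_features))
        y = coef * X[:, planted] + sd * rng.standard_normal(n_rows)
        cols = [f"param_{i}" for i in range(n_features)]
        return SyntheticDataset(
            {"perturbations": pd.DataFrame(X, columns=cols), "response": y},
            {"planted_feature": cols[planted], "coef": coef},
            spec,
        )
    raise SyntheticError(spec.generator)  # unreachable; guarded in spec


# ---------------------------------------------------------------------------
# ISO-like forcing inputs (synthetic stand-ins for the bath-application
# protocols: a slow cAMP bath for isoproterenol, brief high calcium for a
# 100 Hz train, three minutes of moderate calcium for 5 Hz, and the two
# combinations that experimentally produce late-phase LTP)


ISO_CONDITIONS = ("ISO", "100Hz", "5Hz", "ISO+100Hz", "ISO+5Hz")


def generate_iso_like_inputs(
    seed: int = 0,
    out_dir: str | Path | None = None,
    dt: float = 1.0,
    t_total: float = 900.0,
    calcium_basal: float = 50.0,
    camp_basal: float = 30.0,
) -> dict[str, pd.DataFrame]:
    """Synthetic input time series for the five bath/train conditions.

    Returns one tidy frame per condition (columns time_s, species,
    value_nM), loadable by
    :func:`synerk.stimuli.load_timeseries_protocol`.  ``out_dir`` writes
    them as ``synthetic_iso_<condition>.csv``.  A seeded jitter (2%)
    roughens the traces so downstream code cannot rely on exact shapes.
    """
    rng = np.random.default_rng(seed)
    # coarse baseline grid, refined around the 1 s train edges so its
    # duration is honoured regardless of dt
    t = np.unique(np.round(np.concatenate([
        np.arange(0.0, t_total + dt / 2, dt),
        np.arange(299.0, 302.0 + 1e-9, 0.2),
    ]), 6))

    def iso_camp():
        # slow bath ramp: rise over ~60 s, hold ~540 s, washout
        rise = 1.0 - np.exp(-np.clip(t - 100.0, 0.0, None) / 30.0)
        wash = np.exp(-np.clip(t - 640.0, 0.0, None) / 60.0)
        return camp_basal + 470.0 * rise * wash

    def train_calcium(onset, duration, peak):
        out = np.full_like(t, calcium_basal)
        on = (t >= onset) & (t < onset + duration)
        out[on] = peak
        return out

    def jitter(v, basal):
        return np.maximum(v * (1.0 + 0.02 * rng.standard_normal(v.size)), 0.05 * basal)

    # component traces are jittered once and shared between conditions, as
    # if produced by one upstream simulation; the train amplitudes sit below
    # the kinase switch's threshold so no single condition saturates ppERK
    hf_peak, lf_peak = 1500.0, 100.0
    ca_flat = jitter(np.full_like(t, calcium_basal), calcium_basal)
    camp_flat = jitter(np.full_like(t, camp_basal), camp_basal)
    ca_100 = jitter(train_calcium(300.0, 1.0, hf_peak), calcium_basal)
    ca_5 = jitter(train_calcium(300.0, 180.0, lf_peak), calcium_basal)
    camp_iso = jitter(iso_camp(), camp_basal)
    series: dict[str, dict[str, np.ndarray]] = {
        "ISO": {"calcium": ca_flat, "cAMP": camp_iso},
        "100Hz": {"calcium": ca_100, "cAMP": camp_flat},
        "5Hz": {"calcium": ca_5, "cAMP": camp_flat},
        "ISO+100Hz": {"calcium": ca_100, "cAMP": camp_iso},
        "ISO+5Hz": {"calcium": ca_5, "cAMP": camp_iso},
    }

    frames: dict[str, pd.DataFrame] = {}
    for cond, chans in series.items():
        rows = [
            pd.DataFrame({"time_s": t, "species": sp, "value_nM": v})
            for sp, v in chans.items()
        ]
        frames[cond] = pd.concat(rows, ignore_index=True)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for cond, df in frames.items():
            safe = cond.replace("+", "_plus_")
            df.to_csv(out / f"synthetic_iso_{safe}.csv", index=False)
    return frames
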