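"""Summary statistics and statistical tests on simulated trajectories.

Kinase activity is quantified as area under the curve (AUC): the integral
of a species' concentration above its own pre-stimulus baseline.  Dose–
response curves are classified linear vs non-linear by fitting a line, a
logarithmic curve and a Hill equation and comparing adjusted R² and AIC.
Synergy between pathways is tested with a two-way ANCOVA of AUC against the
stimulation covariate and a combination-versus-summation factor.  Parameter
robustness is ranked with random-forest feature importances.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy.optimize import curve_fit
from sklearn.ensemble import RandomForestRegressor

from .simulate import Trajectory
from .stimuli import LLTP_ITIS


class AnalysisError(ValueError):
    pass


# ---------------------------------------------------------------------------
# AUC


@dataclass(frozen=True)
class AucResult:
    species: str
    auc: float               # nM·s above basal
    basal: float             # nM (pre-stimulus mean)
    window: tuple[float, float]
    peak: float              # nM, absolute
    time_to_peak: float      # s after stimulation onset
    time_to_basal: float | None  # s after onset, None if unresolved


def auc_above_basal(
    traj: Trajectory,
    species: str = "ppERK",
    stim_onset: float = 300.0,
    window_end: float | None = None,
    min_baseline: float = 300.0,
    basal_fraction: float = 0.05,
    basal_hold: float = 60.0,
) -> AucResult:
    """AUC of ``species`` above its own pre-stimulus baseline.

    The baseline is the mean over [0, stim_onset), which must span at least
    ``min_baseline`` seconds.  The integral runs from ``stim_onset`` to
    ``window_end`` (default: end of trajectory) over the positive part of
    the baseline-subtracted signal.  ``time_to_basal`` is the first time
    after the peak at which the signal stays within ``basal_fraction`` of
    the baseline for ``basal_hold`` seconds (None if it never does).
    """
    if stim_onset < min_baseline:
        raise AnalysisError(
            f"pre-stimulus window is {stim_onset:g} s; need >= {min_baseline:g} s"
        )
    t = traj.times
    y = traj.series(species)
    t_end = float(t[-1]) if window_end is None else float(window_end)
    if t_end > t[-1] + 1e-9 or stim_onset >= t_end:
        raise AnalysisError(f"window ({stim_onset}, {t_end}) outside trajectory span")
    pre = t < stim_onset
    basal = float(y[pre].mean())
    win = (t >= stim_onset) & (t <= t_end)
    tw, yw = t[win], y[win]
    excess = np.clip(yw - basal, 0.0, None)
    auc = float(np.trapezoid(excess, tw))
    ipk = int(np.argmax(yw))
    peak = float(yw[ipk])
    time_to_peak = float(tw[ipk] - stim_onset)
    # return-to-baseline: sliding check after the peak
    tol = basal_fraction * max(abs(basal), 1e-12)
    time_to_basal = None
    near = np.abs(yw - basal) <= tol
    for i in range(ipk, len(tw)):
        if not near[i]:
            continue
        j = np.searchsorted(tw, tw[i] + basal_hold)
        if j > len(tw) - 1:
            break
        if near[i:j + 1].all():
            time_to_basal = float(tw[i] - stim_onset)
            break
    return AucResult(
        species=species, auc=auc, basal=basal, window=(float(stim_onset), t_end),
        peak=peak, time_to_peak=time_to_peak, time_to_basal=time_to_basal,
    )


# ---------------------------------------------------------------------------
# dose–response model selection


@dataclass(frozen=True)
class FitResult:
    model: str                      # linear | log | hill
    params: dict[str, float]
    param_sd: dict[str, float]
    adjusted_r2: float
    aic: float
    converged: bool
    classification: str             # the class this model implies if chosen

    def __repr__(self) -> str:  # compact report line
        p = ", ".join(f"{k}={v:.4g}" for k, v in self.params.items())
        return (f"FitResult({self.model}: {p}; adjR2={self.adjusted_r2:.4f}, "
                f"AIC={self.aic:.2f})")


@dataclass(frozen=True)
class DoseResponseResult:
    fits: tuple[FitResult, ...]
    classification: str             # linear | non-linear

    def fit(self, model: str) -> FitResult:
        for f in self.fits:
            if f.model == model:
                return f
        raise KeyError(model)


def _hill(x, top, half, n):
    xn = np.power(x, n)
    return top * xn / (xn + np.power(half, n))


def _gof(y, yhat, n_params):
    n = y.size
    rss = float(np.sum((y - yhat) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    dof = n - n_params - 1
    adj = 1.0 - (1.0 - r2) * (n - 1) / dof if dof > 0 else -np.inf
    k = n_params + 1  # + error variance
    aic = n * math.log(max(rss, 1e-300) / n) + 2 * k
    return adj, aic


def fit_dose_response(
    x: Sequence[float],
    y: Sequence[float],
    models: Sequence[str] = ("linear", "log", "hill"),
    linear_r2_cutoff: float = 0.9,
) -> DoseResponseResult:
    """Fit the candidate response models and classify linear vs non-linear.

    ``x`` and ``y`` are flat, trial-level arrays (repeat x for replicate
    trials).  The decision rule: if the linear fit's adjusted R² reaches
    ``linear_r2_cutoff`` the response is linear; otherwise the class of the
    lowest-AIC converged model wins (log and Hill both count non-linear).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise AnalysisError("x and y must have the same length")
    if np.unique(x).size < 4:
        raise AnalysisError("need at least 4 distinct x values")
    fits: list[FitResult] = []
    for model in models:
        if model == "linear":
            A = np.column_stack([np.ones_like(x), x])
            coef, *_ = np.linalg.lstsq(A, y, rcond=None)
            yhat = A @ coef
            adj, aic = _gof(y, yhat, 2)
            resid_var = np.sum((y - yhat) ** 2) / max(y.size - 2, 1)
            cov = resid_var * np.linalg.inv(A.T @ A)
            fits.append(FitResult(
                "linear", {"intercept": coef[0], "slope": coef[1]},
                {"intercept": math.sqrt(cov[0, 0]), "slope": math.sqrt(cov[1, 1])},
                adj, aic, True, "linear",
            ))
        elif model == "log":
            if np.any(x <= 0):
                fits.append(FitResult("log", {}, {}, -np.inf, np.inf, False, "non-linear"))
                continue
            lx = np.log10(x)
            A = np.column_stack([np.ones_like(lx), lx])
            coef, *_ = np.linalg.lstsq(A, y, rcond=None)
            yhat = A @ coef
            adj, aic = _gof(y, yhat, 2)
            resid_var = np.sum((y - yhat) ** 2) / max(y.size - 2, 1)
            cov = resid_var * np.linalg.inv(A.T @ A)
            fits.append(FitResult(
                "log", {"intercept": coef[0], "slope": coef[1]},
                {"intercept": math.sqrt(cov[0, 0]), "slope": math.sqrt(cov[1, 1])},
                adj, aic, True, "non-linear",
            ))
        elif model == "hill":
            fits.append(_fit_hill(x, y))
        else:
            raise AnalysisError(f"unknown model {model!r}")
    converged = [f for f in fits if f.converged]
    linear = next((f for f in fits if f.model == "linear"), None)
    if linear is not None and linear.adjusted_r2 >= linear_r2_cutoff:
        classification = "linear"
    else:
        best = min(converged, key=lambda f: f.aic)
        classification = best.classification
    return DoseResponseResult(tuple(fits), classification)


def _fit_hill(x: np.ndarray, y: np.ndarray) -> FitResult:
    """Hill fit with data-driven initialisation and a small multistart on n."""
    top0 = float(np.max(y))
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    half_level = 0.5 * top0
    above = ys >= half_level
    half0 = float(xs[above][0]) if above.any() else float(np.median(xs))
    best = None
    for n0 in (2.0, 1.0, 4.0):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = curve_fit(
                    _hill, x, y, p0=[top0, max(half0, 1e-6), n0],
                    bounds=([0.0, 1e-9, 1e-3], [np.inf, np.inf, 50.0]),
                    maxfev=20000,
                )
        except (RuntimeError, ValueError):
            continue
        yhat = _hill(x, *popt)
        adj, aic = _gof(y, yhat, 3)
        if best is None or aic < best[2]:
            best = (popt, pcov, aic, adj)
    if best is None:
        return FitResult("hill", {}, {}, -np.inf, np.inf, False, "non-linear")
    popt, pcov, aic, adj = best
    sd = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    return FitResult(
        "hill",
        {"max": popt[0], "half_point": popt[1], "n": popt[2]},
        {"max": sd[0], "half_point": sd[1], "n": sd[2]},
        adj, aic, True, "non-linear",
    )


# ---------------------------------------------------------------------------
# combination vs summation (ANCOVA)


@dataclass(frozen=True)
class AncovaResult:
    f_stat: float
    df: tuple[int, int]          # (model df, residual df)
    p_stim: float
    t_stim: float
    p_type: float
    t_type: float
    type_effect: float           # combo minus summation, adjusted
    verdict: str                 # sublinear | linear | supralinear
    n_per_group: int


def summation_test(
    auc_combo: Sequence[float],
    auc_sum_of_singles: Sequence[float],
    x: Sequence[float],
    alpha: float = 0.05,
) -> AncovaResult:
    """Two-way ANCOVA of AUC against the stimulation covariate and type.

    ``auc_combo``: per-trial AUC of the combined stimulation; ``auc_sum_of_
    singles``: per-trial sum of the single-pathway AUCs; ``x`` the shared
    covariate (duration or intertrain interval), one value per trial.  A
    significant type effect with the combination below the summation is
    sublinear; above, supralinear; otherwise the pathways add linearly.
    """
    combo = np.asarray(auc_combo, float)
    sums = np.asarray(auc_sum_of_singles, float)
    x = np.asarray(x, float)
    if combo.shape != sums.shape or combo.shape != x.shape:
        raise AnalysisError("combo, summation and covariate must be equal length")
    counts = pd.Series(x).value_counts()
    if counts.nunique() != 1:
        raise AnalysisError("unequal trial counts per covariate level")
    df = pd.DataFrame({
        "auc": np.concatenate([combo, sums]),
        "x": np.concatenate([x, x]),
        "kind": ["combination"] * combo.size + ["summation"] * sums.size,
    })
    fit = smf.ols("auc ~ x + C(kind, Treatment('summation'))", data=df).fit()
    type_term = "C(kind, Treatment('summation'))[T.combination]"
    t_type = float(fit.tvalues[type_term])
    p_type = float(fit.pvalues[type_term])
    effect = float(fit.params[type_term])
    if p_type < alpha:
        verdict = "supralinear" if effect > 0 else "sublinear"
    else:
        verdict = "linear"
    return AncovaResult(
        f_stat=float(fit.fvalue),
        df=(int(fit.df_model), int(fit.df_resid)),
        p_stim=float(fit.pvalues["x"]),
        t_stim=float(fit.tvalues["x"]),
        p_type=p_type,
        t_type=t_type,
        type_effect=effect,
        verdict=verdict,
        n_per_group=int(counts.iloc[0]),
    )


# ---------------------------------------------------------------------------
# pathway contributions and temporal sensitivity


def pathway_contribution(
    auc_single_pathways: Mapping[str, float], auc_all: float
) -> dict[str, float]:
    """Percent of the all-pathway response attributable to each single pathway.

    Deliberately unnormalised — the percentages may sum to more than 100
    because pathways interact.
    """
    if auc_all <= 0:
        raise AnalysisError(f"all-pathway AUC must be > 0, got {auc_all}")
    return {p: 100.0 * a / auc_all for p, a in auc_single_pathways.items()}


@dataclass(frozen=True)
class TemporalSensitivity:
    mean: float          # mean AUC across the five ITIs
    sensitivity: float   # max - min across ITIs
    best_iti: float      # argmax; ties resolved toward the larger interval


def temporal_sensitivity(auc_by_iti: Mapping[float, float]) -> TemporalSensitivity:
    """Spread of the response across the five L-LTP intertrain intervals."""
    missing = [iti for iti in LLTP_ITIS if iti not in auc_by_iti]
    if missing:
        raise AnalysisError(f"missing ITIs {missing}; need all of {list(LLTP_ITIS)}")
    vals = np.array([auc_by_iti[iti] for iti in LLTP_ITIS], float)
    best = max(
        (v, iti) for iti, v in zip(LLTP_ITIS, vals)
    )[1]  # tuple order: value first, then ITI -> ties go to the larger ITI
    return TemporalSensitivity(
        mean=float(vals.mean()),
        sensitivity=float(vals.max() - vals.min()),
        best_iti=float(best),
    )


# ---------------------------------------------------------------------------
# robustness (random-forest importances)


@dataclass(frozen=True)
class RobustnessResult:
    feature_names: tuple[str, ...]
    weights: np.ndarray              # non-negative, sums to 1
    ranking: tuple[str, ...]         # features, most to least important
    per_perturbation: pd.DataFrame | None = None
    best_iti_counts: Mapping[float, int] = field(default_factory=dict)

    def weight(self, feature: str) -> float:
        return float(self.weights[self.feature_names.index(feature)])


def robustness_importance(
    perturbations: pd.DataFrame | np.ndarray,
    response: Sequence[float],
    n_trees: int = 100,
    seed: int = 0,
    min_rows: int = 30,
) -> RobustnessResult:
    """Rank parameters by their influence on the response with a forest.

    ``perturbations``: one row per simulation, one column per parameter
    (fractional changes); ``response``: the summary each row produced
    (e.g. temporal sensitivity of ppERK).  Importances come from a
    100-tree random-forest regression and sum to one by construction.
    """
    if isinstance(perturbations, pd.DataFrame):
        X = perturbations.to_numpy(float)
        names = tuple(str(c) for c in perturbations.columns)
    else:
        X = np.asarray(perturbations, float)
        names = tuple(f"param_{i}" for i in range(X.shape[1]))
    yv = np.asarray(response, float)
    if X.shape[0] < min_rows:
        raise AnalysisError(f"need >= {min_rows} perturbation rows, got {X.shape[0]}")
    if X.shape[0] != yv.size:
        raise AnalysisError("perturbations and response length mismatch")
    if np.allclose(yv, yv[0]):
        raise AnalysisError("response is constant; importances are undefined")
    forest = RandomForestRegressor(n_estimators=n_trees, random_state=seed)
    forest.fit(X, yv)
    w = forest.feature_importances_
    order = np.argsort(w)[::-1]
    return RobustnessResult(
        feature_names=names,
        weights=w,
        ranking=tuple(names[i] for i in order),
    )
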