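"""Observation maps, least-squares objective and Nelder-Mead parameter fitting.

The measured series are chi1(t), the mean number of DSBs per cell, and
chi2(t), the mean number of gammaH2AX foci per cell.  The model connects to
them through:

* foci map: one focus is worth ``Zmax`` gammaH2AX molecules, so a solution
  with per-site mean mZ over ``n_dsb0`` initial breaks predicts
  ``foci = n_dsb0 * mZ / Zmax`` (total phosphorylated, mZ + mQ, when an
  antibody extension is active and bound gammaH2AX is stained);
* no-H2AX reference: repair without H2AX is about 10x slower, encoded by
  the time-dilated series ``chi1_bar(t) = chi1(t / 10)``, which is fitted
  by the model solved with k5 = 0 (barred solution).

The objective sums squared residuals of the three channels
(chi1 vs n_dsb0 mX, chi2 vs the foci map, chi1_bar vs the barred
n_dsb0 mX), each channel normalised by the square of its first observation
(or of its maximum, when the first observation is zero, as for foci at the
moment of irradiation).  A soft penalty discourages parameter sets whose
peak mean pATM exceeds the assumed per-site maximum ``Ymax``.

Minimisation is Nelder-Mead in log-parameter space (positivity by
construction) with optional multi-start restarts drawn log-uniformly
around the initial guess.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .model_core import AssumedConstants, ExtensionRates, RateConstants, stability_check
from .moment_odes import MeanState, integrate

__all__ = [
    "TimeSeriesObservations",
    "FitResult",
    "foci_from_model",
    "no_h2ax_reference",
    "objective",
    "fit_baseline",
    "fit_antibody_grouping",
]

logger = logging.getLogger(__name__)

_FAILURE_OBJECTIVE = 1e12  # large finite value returned on integrator failure
_YMAX_PENALTY = 1e4  # weight of the soft Ymax excursion penalty


@dataclass(frozen=True)
class TimeSeriesObservations:
    """Per-cell mean DSB (chi1) and focus (chi2) counts on a time grid (h).

    Missing values are NaN and are masked in the objective.  ``chi1_bar``
    optionally holds a no-H2AX reference series; when absent it is
    constructed by :func:`no_h2ax_reference`.  ``tat0`` and ``R`` annotate
    the experimental condition of the series.
    """

    t: np.ndarray
    chi1: np.ndarray
    chi2: np.ndarray
    chi1_bar: Optional[np.ndarray] = None
    tat0: float = 0.0
    R: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        object.__setattr__(self, "t", t)
        for name in ("chi1", "chi2", "chi1_bar"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                object.__setattr__(self, name, v)
                if v.shape != t.shape:
                    raise ValueError(f"{name} must share the time grid")
                if np.nanmin(v, initial=0.0) < 0:
                    raise ValueError(f"{name} contains negative counts")
        if t.ndim != 1 or t.size == 0:
            raise ValueError("need a 1-D, non-empty time grid")
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValueError("times must be non-negative and strictly increasing")


@dataclass(frozen=True)
class FitResult:
    """Outcome of a parameter fit."""

    rates: RateConstants
    objective: float
    converged: bool
    n_evals: int
    trace: tuple = ()  # per start: (index, start objective, final objective, final rates dict)
    constants: AssumedConstants = AssumedConstants()
    closure: str = "conditional"
    seed: Optional[int] = None
    grouping: Optional[float] = None  # g = k8 * tat0 / k7 for antibody fits


def foci_from_model(mZ, n_dsb0: int = 160, zmax: float = AssumedConstants().Zmax):
    """Map a mean gammaH2AX series to a per-cell focus count.

    One focus is taken to contain ``zmax`` molecules, so
    ``foci = n_dsb0 * mZ / zmax``.  Pass total phosphorylated (mZ + mQ)
    when antibody-bound gammaH2AX is stained.
    """
    if zmax <= 0:
        raise ValueError("zmax must be > 0")
    return n_dsb0 * np.asarray(mZ, dtype=float) / zmax


def no_h2ax_reference(t, chi1, slowdown: float = 10.0) -> np.ndarray:
    """Time-dilated reference series chi1(t / slowdown).

    Emulates the ~10-fold slower repair observed without H2AX.  ``chi1`` is
    linearly interpolated; the initial value is held for arguments before
    the first observation, the final value after the last (so
    ``chi1_bar(0) = chi1(0)`` for any slowdown).
    """
    t = np.asarray(t, dtype=float)
    chi1 = np.asarray(chi1, dtype=float)
    if t.size == 0:
        raise ValueError("empty series")
    if slowdown <= 0:
        raise ValueError("slowdown must be > 0")
    valid = ~np.isnan(chi1)
    if not valid.any():
        raise ValueError("chi1 has no observed values")
    return np.interp(t / slowdown, t[valid], chi1[valid])


def _channel_scale(series: np.ndarray) -> float:
    """First observation if positive, else the series maximum (unit scale
    as a last resort for an all-zero channel)."""
    valid = series[~np.isnan(series)]
    if valid.size == 0:
        return 1.0
    first = valid[0]
    if first > 0:
        return float(first)
    m = valid.max()
    return float(m) if m > 0 else 1.0


def _masked_ssr(obs: np.ndarray, model: np.ndarray) -> float:
    mask = ~np.isnan(obs)
    scale = _channel_scale(obs)
    r = (obs[mask] - model[mask]) / scale
    with np.errstate(over="ignore"):
        return float(np.dot(r, r))


def objective(
    params: RateConstants,
    data: TimeSeriesObservations,
    constants: AssumedConstants = AssumedConstants(),
    closure: str = "conditional",
    barred_closure: str = "naive",
    n_dsb0: int = 160,
    ext: Optional[ExtensionRates] = None,
    count_bound: bool = True,
    slowdown: float = 10.0,
    rtol: float = 1e-7,
    atol: float = 1e-9,
    require_stable: bool = True,
) -> float:
    """Least-squares error of ``params`` against the observed series.

    Solves the chosen closure with the full parameter set and, for the
    no-H2AX channel, with ``k5 = 0`` (``barred_closure``; the barred branch
    defaults to the independence closure).  Returns a large finite value on
    integrator failure so direct-search optimisers can proceed; with
    ``require_stable`` (default) parameter sets violating the decay
    condition k3 k5 < k4 k6 — which can never reach the repaired
    zero steady state — are rejected the same way without integration.
    """
    if require_stable and not stability_check(params)[0]:
        return _FAILURE_OBJECTIVE
    grid = data.t if data.t[0] == 0.0 else np.concatenate(([0.0], data.t))
    take = slice(1, None) if data.t[0] != 0.0 else slice(None)
    if grid.size < 2:
        grid = np.array([0.0, max(1e-3, float(data.t[-1]))])
        take = slice(0, 1)
    try:
        with np.errstate(over="ignore", invalid="ignore"):
            sol = integrate(closure, params, ext=ext, grid=grid, rtol=rtol, atol=atol)
            sol_bar = integrate(barred_closure, params.replace(k5=0.0), ext=None,
                                grid=grid, rtol=rtol, atol=atol)
    except (RuntimeError, ValueError, FloatingPointError, OverflowError):
        return _FAILURE_OBJECTIVE
    if not all(np.all(np.isfinite(a)) for a in (sol.mX, sol.mY, sol.mZ, sol.mQ, sol_bar.mX)):
        return _FAILURE_OBJECTIVE
    mZ_total = sol.mZ + (sol.mQ if (ext is not None and count_bound) else 0.0)
    model_chi1 = n_dsb0 * sol.mX[take]
    model_chi2 = foci_from_model(mZ_total, n_dsb0, constants.Zmax)[take]
    model_chi1_bar = n_dsb0 * sol_bar.mX[take]
    chi1_bar = (data.chi1_bar if data.chi1_bar is not None
                else no_h2ax_reference(data.t, data.chi1, slowdown))
    total = (
        _masked_ssr(data.chi1, model_chi1)
        + _masked_ssr(data.chi2, model_chi2)
        + _masked_ssr(chi1_bar, model_chi1_bar)
    )
    peak_y = float(np.max(sol.mY))
    if peak_y > constants.Ymax:
        with np.errstate(over="ignore"):
            total += float(_YMAX_PENALTY * np.square((peak_y - constants.Ymax) / constants.Ymax))
    if not np.isfinite(total):
        return _FAILURE_OBJECTIVE
    return total


_RATE_NAMES = ("k1", "k2", "k3", "k4", "k5", "k6")


def fit_baseline(
    data: TimeSeriesObservations,
    constants: AssumedConstants = AssumedConstants(),
    init_guess: Optional[RateConstants] = None,
    closure: str = "conditional",
    n_dsb0: int = 160,
    restarts: int = 0,
    spread_decades: float = 2.0,
    max_iter: int = 4000,
    polish_rounds: int = 4,
    anchor_scale: bool = True,
    seed: int = 0,
    **obj_kw,
) -> FitResult:
    """Fit the six core rates to (chi1, chi2) by Nelder-Mead.

    The search runs in log-parameter space; ``restarts`` additional starts
    are drawn log-uniformly within ``spread_decades`` decades of the
    initial guess (deterministic given ``seed``).  Each start's simplex is
    re-initialised at its own endpoint up to ``polish_rounds`` times (the
    standard remedy for Nelder-Mead simplex collapse in >3 dimensions).
    The best result is returned, flagged non-converged if no start
    satisfied the simplex convergence test.

    Gauge fixing: the observation channels are exactly invariant under the
    one-parameter scaling ``(k1, k2, k3, k5) -> (c k1, k2/c, k3/c, c k5)``
    — the absolute scale of the unobserved pATM count is not identifiable
    from DSB/foci series.  With ``anchor_scale`` (default) the converged
    parameters are slid along this orbit to the log-space point nearest the
    initial guess (closed form), re-polished, and kept if not worse; this
    selects a well-defined representative of the optimal orbit instead of
    an arbitrary point on the flat valley.
    """
    if init_guess is None:
        init_guess = RateConstants(k1=0.01, k2=500.0, k3=50.0, k4=300.0, k5=1000.0, k6=300.0)
    theta0 = np.log([getattr(init_guess, k) for k in _RATE_NAMES])
    rng = np.random.default_rng(seed)
    starts = [theta0] + [
        theta0 + rng.uniform(-spread_decades, spread_decades, 6) * np.log(10.0)
        for _ in range(restarts)
    ]

    def f(theta: np.ndarray) -> float:
        if np.any(theta > 50):  # exp overflow guard
            return _FAILURE_OBJECTIVE
        rates = RateConstants(**dict(zip(_RATE_NAMES, np.exp(theta))))
        return objective(rates, data, constants, closure=closure, n_dsb0=n_dsb0, **obj_kw)

    best = None
    trace = []
    n_evals = 0
    opts = {"maxiter": max_iter, "xatol": 1e-6, "fatol": 1e-12, "adaptive": True}
    # orbit direction in log space: +log c on (k1, k5), -log c on (k2, k3)
    orbit = np.array([1.0, -1.0, -1.0, 0.0, 1.0, 0.0])
    for i, th in enumerate(starts):
        res = minimize(f, th, method="Nelder-Mead", options=opts)
        n_evals += res.nfev
        for _ in range(polish_rounds):
            prev = res.fun
            res2 = minimize(f, res.x, method="Nelder-Mead", options=opts)
            n_evals += res2.nfev
            if res2.fun < res.fun:
                res = res2
            if prev - res.fun <= 1e-12 + 1e-6 * abs(prev):
                break
        x_fin, f_fin, success = res.x, float(res.fun), bool(res.success)
        if anchor_scale:
            # closed-form slide to the orbit point nearest the initial guess;
            # adopt it when the valley is flat there (within 5%), since the
            # objective is exactly orbit-invariant up to noise-induced tilt
            log_c = -float(orbit @ (x_fin - theta0)) / 4.0
            cand = x_fin + orbit * log_c
            f_cand = f(cand)
            n_evals += 1
            if f_cand <= f_fin * 1.05 + 1e-12:
                x_fin, f_fin = cand, f_cand
        trace.append((i, float(f(th)), f_fin, dict(zip(_RATE_NAMES, np.exp(x_fin)))))
        if best is None or f_fin < best[1]:
            best = (x_fin, f_fin, success)
        logger.debug("start %d: objective %.3e -> %.3e", i, trace[-1][1], trace[-1][2])
    rates = RateConstants(**dict(zip(_RATE_NAMES, np.exp(best[0]))))
    return FitResult(
        rates=rates, objective=float(best[1]), converged=best[2],
        n_evals=n_evals, trace=tuple(trace), constants=constants,
        closure=closure, seed=seed,
    )


def fit_antibody_grouping(
    panels: Sequence[TimeSeriesObservations],
    baseline: RateConstants,
    constants: AssumedConstants = AssumedConstants(),
    k7_ref: float = 1.0,
    closure: str = "naive",
    n_dsb0: int = 160,
    count_bound: bool = True,
    trend_subset: Optional[Sequence[float]] = None,
    rtol: float = 1e-7,
    atol: float = 1e-9,
) -> tuple[list[tuple[float, float]], dict]:
    """Per-concentration fit of the antibody grouping g = k8 [TAT]0 / k7.

    With the core rates fixed at ``baseline``, each panel (annotated with
    its concentration ``tat0``) yields a one-dimensional least-squares fit
    of g to the focus series through the antibody-extended closure; only g
    enters at binding quasi-equilibrium, so the dissociation rate is fixed
    at the reference ``k7_ref`` and ``k8 = g k7 / tat0`` is implied.

    Returns the (tat0, g) pairs and, when at least two concentrations are
    available, the slope/intercept/R^2 of g against tat0 over
    ``trend_subset`` (default: all concentrations).
    """
    results: list[tuple[float, float]] = []
    for obs in panels:
        if obs.tat0 == 0:
            results.append((0.0, 0.0))
            continue

        def f(log_g: float, _obs=obs) -> float:
            g = float(np.exp(log_g))
            ext = ExtensionRates(k7=k7_ref, k8=g * k7_ref / _obs.tat0, tat0=_obs.tat0)
            try:
                sol = integrate(closure, baseline, ext=ext, grid=_obs.t if _obs.t[0] == 0
                                else np.concatenate(([0.0], _obs.t)), rtol=rtol, atol=atol)
            except (RuntimeError, ValueError):
                return _FAILURE_OBJECTIVE
            take = slice(1, None) if _obs.t[0] != 0 else slice(None)
            mZ_total = sol.mZ + (sol.mQ if count_bound else 0.0)
            model = foci_from_model(mZ_total, n_dsb0, constants.Zmax)[take]
            return _masked_ssr(_obs.chi2, model)

        res = minimize_scalar(f, bounds=(np.log(1e-6), np.log(1e3)), method="bounded",
                              options={"xatol": 1e-8})
        results.append((float(obs.tat0), float(np.exp(res.x))))

    trend: dict = {}
    pairs = results if trend_subset is None else [
        p for p in results if any(np.isclose(p[0], c) for c in trend_subset)
    ]
    if len(pairs) >= 2:
        x = np.array([p[0] for p in pairs])
        y = np.array([p[1] for p in pairs])
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
        trend = {"slope": float(slope), "intercept": float(intercept), "r_squared": r2,
                 "n_concentrations": len(pairs)}
    else:
        logger.warning("fewer than 2 concentrations; linear trend not computed")
    return results, trend
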