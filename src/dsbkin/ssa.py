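"""Exact stochastic simulation (Gillespie direct method) of the repair network.

Simulates the single-site jump process defined in :mod:`dsbkin.model_core`,
builds ensemble statistics, and performs the detectable-foci thresholding
analysis (a focus is visible when its gammaH2AX count exceeds ``Zstar``).

Reproducibility: every simulation takes an integer seed.  Ensembles derive
one 32-bit sub-seed per replicate from the master seed through
``numpy.random.SeedSequence(seed).generate_state(n_reps)``, so replicate
``r`` is reproducible in isolation and independent of execution order.

The inner loops are compiled with numba; trajectories are recorded by
right-continuous step sampling onto the user grid (the value at ``t`` is the
state after the last event at or before ``t``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from numba import njit

from .model_core import AssumedConstants, ExtensionRates, RateConstants, SiteState

__all__ = [
    "Trajectory",
    "EnsembleSummary",
    "simulate_site",
    "ensemble",
    "detectable_foci",
    "simulate_population",
]


@dataclass(frozen=True)
class Trajectory:
    """One SSA sample path sampled onto a time grid (hours)."""

    t: np.ndarray
    X: np.ndarray
    Y: np.ndarray
    Z: np.ndarray
    Q: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_h": self.t, "X": self.X, "Y": self.Y, "Z": self.Z, "Q": self.Q})


@dataclass(frozen=True)
class EnsembleSummary:
    """Replicate-averaged trajectories with Monte-Carlo standard errors.

    ``samples`` optionally holds the per-replicate (Z, Q) matrices
    (shape ``(n_reps, len(t))``) needed for foci thresholding.
    """

    t: np.ndarray
    mean_X: np.ndarray
    mean_Y: np.ndarray
    mean_Z: np.ndarray
    mean_Q: np.ndarray
    se_X: np.ndarray
    se_Y: np.ndarray
    se_Z: np.ndarray
    se_Q: np.ndarray
    n_reps: int
    samples: Optional[dict] = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.t,
                "mean_X": self.mean_X,
                "mean_Y": self.mean_Y,
                "mean_Z": self.mean_Z,
                "mean_Q": self.mean_Q,
                "se_X": self.se_X,
                "se_Y": self.se_Y,
                "se_Z": self.se_Z,
                "se_Q": self.se_Q,
            }
        )


@njit(cache=True)
def _ssa_site_kernel(k1, k2, k3, k4, k5, k6, k8tat0, k7, X0, Y0, Z0, Q0, grid, seed):
    """Direct-method SSA for one site; returns state arrays on ``grid``."""
    np.random.seed(seed)
    X, Y, Z, Q = X0, Y0, Z0, Q0
    t = 0.0
    n = grid.shape[0]
    oX = np.empty(n, np.int64)
    oY = np.empty(n, np.int64)
    oZ = np.empty(n, np.int64)
    oQ = np.empty(n, np.int64)
    i = 0
    while i < n:
        a0 = k1 * Y * X
        a1 = k2 * X + k3 * Z
        a2 = k4 * Y
        a3 = k5 * Y
        a4 = k6 * Z
        a5 = k8tat0 * Z
        a6 = k7 * Q
        atot = a0 + a1 + a2 + a3 + a4 + a5 + a6
        if not np.isfinite(atot):
            # signal a numerical failure with the offending state
            return oX[:0], oY[:0], oZ[:0], oQ[:0]
        if atot <= 0.0:
            tnext = np.inf
        else:
            tnext = t + np.random.exponential(1.0 / atot)
        while i < n and grid[i] < tnext:
            oX[i] = X
            oY[i] = Y
            oZ[i] = Z
            oQ[i] = Q
            i += 1
        if i >= n or atot <= 0.0:
            break
        t = tnext
        r = np.random.random() * atot
        if r < a0:
            X = 0
        elif r < a0 + a1:
            Y += 1
        elif r < a0 + a1 + a2:
            Y -= 1
        elif r < a0 + a1 + a2 + a3:
            Z += 1
        elif r < a0 + a1 + a2 + a3 + a4:
            Z -= 1
        elif r < a0 + a1 + a2 + a3 + a4 + a5:
            Z -= 1
            Q += 1
        else:
            Z += 1
            Q -= 1
    return oX, oY, oZ, oQ


def _check_grid(grid) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0 or grid[0] != 0.0:
        raise ValueError("time grid must be 1-D and start at 0")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("time grid must be strictly increasing")
    return grid


def _ext_rates(ext: Optional[ExtensionRates]) -> tuple[float, float]:
    if ext is None:
        return 0.0, 0.0
    return ext.k8 * ext.tat0, ext.k7


def simulate_site(
    rates: RateConstants,
    ext: Optional[ExtensionRates] = None,
    init: SiteState = SiteState(1, 0, 0, 0),
    grid=np.linspace(0.0, 24.0, 97),
    seed: int = 0,
) -> Trajectory:
    """Exact SSA sample path of the single-site process on ``grid``.

    The simulation stops when all propensities vanish (the absorbed
    repaired state) or the grid end is reached.  Identical inputs and seed
    give an identical trajectory.
    """
    grid = _check_grid(grid)
    k8tat0, k7 = _ext_rates(ext)
    oX, oY, oZ, oQ = _ssa_site_kernel(
        rates.k1, rates.k2, rates.k3, rates.k4, rates.k5, rates.k6,
        k8tat0, k7, init.X, init.Y, init.Z, init.Q,
        grid, np.uint32(seed),
    )
    if oX.size != grid.size:
        raise FloatingPointError(
            f"non-finite propensity encountered (rates={rates}, init={init})"
        )
    return Trajectory(grid, oX, oY, oZ, oQ)


def ensemble(
    rates: RateConstants,
    ext: Optional[ExtensionRates] = None,
    init: SiteState = SiteState(1, 0, 0, 0),
    grid=np.linspace(0.0, 24.0, 97),
    n_reps: int = 1000,
    seed: int = 0,
    keep_samples: bool = False,
) -> EnsembleSummary:
    """Replicate-wise means and standard errors over ``n_reps`` SSA runs.

    Per-replicate seeds are spawned from ``seed`` (see module docstring).
    With ``keep_samples=True`` the per-replicate Z and Q matrices are kept
    on the summary so :func:`detectable_foci` can threshold them.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2 for standard errors")
    grid = _check_grid(grid)
    sub = np.random.SeedSequence(seed).generate_state(n_reps)
    mats = {k: np.empty((n_reps, grid.size)) for k in "XYZQ"}
    for r in range(n_reps):
        try:
            traj = simulate_site(rates, ext, init, grid, int(sub[r]))
        except FloatingPointError as e:  # pragma: no cover - defensive
            raise FloatingPointError(f"replicate {r}: {e}") from e
        mats["X"][r] = traj.X
        mats["Y"][r] = traj.Y
        mats["Z"][r] = traj.Z
        mats["Q"][r] = traj.Q
    mean = {k: m.mean(axis=0) for k, m in mats.items()}
    se = {k: m.std(axis=0, ddof=1) / np.sqrt(n_reps) for k, m in mats.items()}
    return EnsembleSummary(
        t=grid,
        mean_X=mean["X"], mean_Y=mean["Y"], mean_Z=mean["Z"], mean_Q=mean["Q"],
        se_X=se["X"], se_Y=se["Y"], se_Z=se["Z"], se_Q=se["Q"],
        n_reps=n_reps,
        samples={"Z": mats["Z"], "Q": mats["Q"]} if keep_samples else None,
    )


def detectable_foci(
    summary: EnsembleSummary,
    zstar: float = AssumedConstants().Zstar,
    n_dsb: int = 160,
    count_bound: bool = True,
) -> np.ndarray:
    """Expected number of microscope-visible foci per cell over time.

    A focus is detectable when its gammaH2AX count exceeds the threshold
    ``zstar``; the expected visible count in a population of ``n_dsb``
    damage sites is ``n_dsb * P(Z >= zstar)``, estimated over the ensemble.
    With ``count_bound`` (default) antibody-bound gammaH2AX contributes to
    the stain, i.e. the threshold is applied to Z + Q.
    """
    if zstar <= 0 or n_dsb <= 0:
        raise ValueError("zstar and n_dsb must be > 0")
    if summary.samples is None:
        raise ValueError("summary lacks per-replicate samples; rerun ensemble(keep_samples=True)")
    total = summary.samples["Z"] + (summary.samples["Q"] if count_bound else 0)
    return n_dsb * (total >= zstar).mean(axis=0)


@njit(cache=True)
def _ssa_population_kernel(k1, k2, k3, k4, k5, k6, k8tat0, k7, k9,
                           X, Y, Z, Q, grid, seed):
    """Direct-method SSA over N sites with Auger re-damage coupling.

    New DSBs are initiated at population hazard (k9 / N) * sum(Q) * n_off,
    landing on a uniformly chosen undamaged site, so the per-site mean obeys
    dmX/dt = k9 * mQ * (1 - mX) in the mean-field limit.
    """
    np.random.seed(seed)
    N = X.shape[0]
    n = grid.shape[0]
    oX = np.empty(n)
    oY = np.empty(n)
    oZ = np.empty(n)
    oQ = np.empty(n)
    t = 0.0
    i = 0
    a = np.empty(5 * N + 1)
    while i < n:
        sumQ = 0
        n_off = 0
        for s in range(N):
            a[5 * s] = k1 * Y[s] * X[s]
            a[5 * s + 1] = k2 * X[s] + k3 * Z[s]
            a[5 * s + 2] = k4 * Y[s]
            a[5 * s + 3] = k5 * Y[s] + k8tat0 * Z[s] + k7 * Q[s]
            # slot 3 bundles phos/bind/unbind resolved below; slot 4 dephos
            a[5 * s + 4] = k6 * Z[s]
            sumQ += Q[s]
            n_off += 1 - X[s]
        a[5 * N] = k9 * sumQ * n_off / N
        atot = a.sum()
        if atot <= 0.0:
            tnext = np.inf
        else:
            tnext = t + np.random.exponential(1.0 / atot)
        while i < n and grid[i] < tnext:
            sx = 0.0; sy = 0.0; sz = 0.0; sq = 0.0
            for s in range(N):
                sx += X[s]; sy += Y[s]; sz += Z[s]; sq += Q[s]
            oX[i] = sx / N; oY[i] = sy / N; oZ[i] = sz / N; oQ[i] = sq / N
            i += 1
        if i >= n or atot <= 0.0:
            break
        t = tnext
        r = np.random.random() * atot
        j = 0
        acc = a[0]
        while acc < r and j < 5 * N:
            j += 1
            acc += a[j]
        if j == 5 * N:
            # de novo DSB at a random undamaged site
            pick = int(np.random.random() * n_off)
            for s in range(N):
                if X[s] == 0:
                    if pick == 0:
                        X[s] = 1
                        break
                    pick -= 1
        else:
            s = j // 5
            kind = j % 5
            if kind == 0:
                X[s] = 0
            elif kind == 1:
                Y[s] += 1
            elif kind == 2:
                Y[s] -= 1
            elif kind == 3:
                # resolve the bundled Z-channel: phosphorylate / bind / unbind
                r2 = np.random.random() * (k5 * Y[s] + k8tat0 * Z[s] + k7 * Q[s])
                if r2 < k5 * Y[s]:
                    Z[s] += 1
                elif r2 < k5 * Y[s] + k8tat0 * Z[s]:
                    Z[s] -= 1
                    Q[s] += 1
                else:
                    Z[s] += 1
                    Q[s] -= 1
            else:
                Z[s] -= 1
    return oX, oY, oZ, oQ


def simulate_population(
    rates: RateConstants,
    ext: Optional[ExtensionRates] = None,
    n_sites: int = 160,
    n_damaged: Optional[int] = None,
    grid=np.linspace(0.0, 24.0, 97),
    seed: int = 0,
) -> Trajectory:
    """SSA over a population of ``n_sites`` DNA sites, returning per-site means.

    This is the stochastic counterpart of the Auger mean-field system:
    antibody-bound gammaH2AX anywhere in the population initiates de novo
    DSBs at uniformly chosen undamaged sites (hazard documented on the
    kernel).  ``n_damaged`` sites start with a break (default: all).
    Without an extension (or with ``k9 = 0``) sites are independent and the
    result is an unbiased per-site average of the baseline process.
    """
    grid = _check_grid(grid)
    if n_damaged is None:
        n_damaged = n_sites
    if not 0 <= n_damaged <= n_sites:
        raise ValueError("need 0 <= n_damaged <= n_sites")
    k8tat0, k7 = _ext_rates(ext)
    k9 = ext.k9 if ext is not None else 0.0
    X = np.zeros(n_sites, np.int64)
    X[:n_damaged] = 1
    Y = np.zeros(n_sites, np.int64)
    Z = np.zeros(n_sites, np.int64)
    Q = np.zeros(n_sites, np.int64)
    oX, oY, oZ, oQ = _ssa_population_kernel(
        rates.k1, rates.k2, rates.k3, rates.k4, rates.k5, rates.k6,
        k8tat0, k7, k9, X, Y, Z, Q, grid, np.uint32(seed),
    )
    return Trajectory(grid, oX, oY, oZ, oQ)
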