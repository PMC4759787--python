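"""Mean-field moment-closure reductions of the single-site master equation.

Writing ``mX = <X>``, ``mY = <Y>``, ``mZ = <Z>`` for the stochastic means,
differentiating the master equation gives

    d<X>/dt = -k1 <XY>
    d<Y>/dt =  k2 <X> + k3 <Z> - k4 <Y>
    d<Z>/dt =  k5 <Y> - k6 <Z>

Only the first equation is unclosed.  Two closures are provided:

**Independence (naive) closure** — assume <XY> = <X><Y>, i.e. the damage
indicator and the repair-molecule count are uncorrelated:

    dmX/dt = -k1 mX mY.

**Conditional-mean closure** — introduce the conditional means
``u = E[Y | X=1]``, ``v = E[Z | X=1]``, ``w = E[Y | X=0]``,
``s = E[Z | X=0]`` so that <XY> = mX u exactly, and close by neglecting the
conditional (co)variances.  The derivation (carried out from the jump rates;
see docs/methods.md) gives

    dmX/dt = -k1 mX u
    du/dt  =  k2 + k3 v - k4 u
    dv/dt  =  k5 u - k6 v
    dw/dt  =  k3 s - k4 w + k1 u mX (u - w) / (1 - mX)
    ds/dt  =  k5 w - k6 s + k1 u mX (v - s) / (1 - mX)

The (u, v) equations decouple because the probability flux leaving the
damaged population carries means (u, v), which cancel under the
zero-variance closure; the same flux enters the repaired population,
producing the relaxation terms in (w, s).  Unconditional means follow from
the mixture identities ``mY = mX u + (1-mX) w``, ``mZ = mX v + (1-mX) s``.

**Antibody extension** — anti-gammaH2AX-TAT at concentration [TAT]0 binds
free gammaH2AX reversibly into an inert pool ``Q``:

    dmQ/dt = k8 [TAT]0 mZ - k7 mQ,

with the matching sink/source in dmZ/dt and no Q contribution to
recruitment or repair.

**Auger extension** — when the antibody carries 111In at specific activity
R, each bound molecule initiates de novo DSBs at rate ``k9 = kappa R``;
under mean-field independence of damage location the undamaged fraction is
converted at

    dmX/dt += k9 mQ (1 - mX),

built on the naive closure (population size absorbed into k9).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model_core import ExtensionRates, RateConstants, stability_check

__all__ = [
    "MeanState",
    "OdeSolution",
    "rhs_naive",
    "rhs_conditional",
    "rhs_antibody",
    "rhs_auger",
    "integrate",
    "persistence_auc",
]

# below this repaired-population weight the (w, s) branch means are frozen:
# they multiply a vanishing weight in the mixture identities.
_BRANCH_EPS = 1e-12


@dataclass(frozen=True)
class MeanState:
    """Expected state of a damage site under a mean-field closure.

    ``u, v, w, s`` are the conditional means of (Y, Z) given X=1 / X=0 and
    are populated only by the conditional closure.
    """

    mX: float
    mY: float
    mZ: float
    mQ: float = 0.0
    u: Optional[float] = None
    v: Optional[float] = None
    w: Optional[float] = None
    s: Optional[float] = None


@dataclass(frozen=True)
class OdeSolution:
    """Mean trajectories on a time grid, with solver diagnostics."""

    t: np.ndarray
    mX: np.ndarray
    mY: np.ndarray
    mZ: np.ndarray
    mQ: np.ndarray
    u: Optional[np.ndarray] = None
    v: Optional[np.ndarray] = None
    w: Optional[np.ndarray] = None
    s: Optional[np.ndarray] = None
    closure: str = "naive"
    diagnostics: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"time_h": self.t, "mean_X": self.mX, "mean_Y": self.mY,
             "mean_Z": self.mZ, "mean_Q": self.mQ}
        )
        if self.u is not None:
            df["u"], df["v"], df["w"], df["s"] = self.u, self.v, self.w, self.s
        return df


def rhs_naive(m: Sequence[float], rates: RateConstants) -> np.ndarray:
    """Time derivative of (mX, mY, mZ) under the independence closure."""
    mX, mY, mZ = m
    return np.array(
        [
            -rates.k1 * mX * mY,
            rates.k2 * mX + rates.k3 * mZ - rates.k4 * mY,
            rates.k5 * mY - rates.k6 * mZ,
        ]
    )


def rhs_conditional(m: Sequence[float], rates: RateConstants) -> np.ndarray:
    """Time derivative of (mX, u, v, w, s) under the conditional-mean closure.

    When a branch population is empty (mX at 0 or 1) its conditional means
    are frozen (zero derivative): they carry zero weight in the mixture
    identities, so the unconditional means are unaffected.
    """
    mX, u, v, w, s = m
    du = rates.k2 + rates.k3 * v - rates.k4 * u
    dv = rates.k5 * u - rates.k6 * v
    q = 1.0 - mX
    if q > _BRANCH_EPS:
        flux = rates.k1 * u * mX / q
        dw = rates.k3 * s - rates.k4 * w + flux * (u - w)
        ds = rates.k5 * w - rates.k6 * s + flux * (v - s)
    else:
        dw = ds = 0.0
    if mX <= _BRANCH_EPS:
        du = dv = 0.0
    return np.array([-rates.k1 * mX * u, du, dv, dw, ds])


def rhs_antibody(
    m: Sequence[float], rates: RateConstants, ext: ExtensionRates, closure: str = "naive"
) -> np.ndarray:
    """Antibody-extended derivative.

    Naive closure state: (mX, mY, mZ, mQ); conditional closure state:
    (mX, u, v, w, s, mQ), treating Q as independent of X (the bound complex
    is inert, so its only coupling to the branches is the Z exchange flux).
    With ``tat0 = 0`` and ``mQ = 0`` the output reduces exactly to the
    unextended closure.
    """
    bind_rate = ext.k8 * ext.tat0
    if closure == "naive":
        mX, mY, mZ, mQ = m
        d = rhs_naive((mX, mY, mZ), rates)
        exch = bind_rate * mZ - ext.k7 * mQ
        return np.array([d[0], d[1], d[2] - exch, exch])
    elif closure == "conditional":
        mX, u, v, w, s, mQ = m
        d = rhs_conditional((mX, u, v, w, s), rates)
        # per-branch Z loses to binding and gains from the (branch-blind)
        # unbound pool; the mixture recovers dmZ -= exch exactly
        d[2] += -bind_rate * v + ext.k7 * mQ
        if 1.0 - mX > _BRANCH_EPS:
            d[4] += -bind_rate * s + ext.k7 * mQ
        mZ = mX * v + (1.0 - mX) * s
        exch = bind_rate * mZ - ext.k7 * mQ
        return np.append(d, exch)
    raise ValueError(f"unknown closure {closure!r}")


def rhs_auger(m: Sequence[float], rates: RateConstants, ext: ExtensionRates) -> np.ndarray:
    """Auger-extended derivative on state (mX, mY, mZ, mQ), naive closure.

    Adds the de novo damage term ``+ k9 mQ (1 - mX)``; with ``R = 0``
    (``k9 = 0``) it coincides with :func:`rhs_antibody`.
    """
    d = rhs_antibody(m, rates, ext, closure="naive")
    d[0] += ext.k9 * m[3] * (1.0 - m[0])
    return d


def _initial_vector(closure: str, ext: Optional[ExtensionRates], init: Optional[MeanState]):
    if init is None:
        init = MeanState(mX=1.0, mY=0.0, mZ=0.0, mQ=0.0)
    if closure == "conditional":
        u = init.u if init.u is not None else init.mY
        v = init.v if init.v is not None else init.mZ
        y0 = [init.mX, u, v, init.mY, init.mZ]
    else:
        y0 = [init.mX, init.mY, init.mZ]
    if ext is not None:
        y0.append(init.mQ)
    return np.array(y0, dtype=float)


def integrate(
    closure: str,
    rates: RateConstants,
    ext: Optional[ExtensionRates] = None,
    init: Optional[MeanState] = None,
    grid=np.linspace(0.0, 24.0, 241),
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> OdeSolution:
    """Integrate the chosen closure ('naive' or 'conditional') on ``grid``.

    The extension terms are applied whenever ``ext`` is given; a non-zero
    ``ext.k9`` (Auger re-damage) requires the naive closure, on which that
    extension is built.

    Numerical note: the conditional closure is integrated in the equivalent
    non-singular variables (mX, u, v, mY, mZ[, mQ]) — the unconditional
    mean equations are exact and linear once <XY> = mX u is closed — and
    the repaired-branch means (w, s) are recovered from the mixture
    identities, frozen at the damaged-branch values while the repaired
    population weight is below 1e-12.
    """
    if closure not in ("naive", "conditional"):
        raise ValueError(f"unknown closure {closure!r}")
    k9 = ext.k9 if ext is not None else 0.0
    if k9 > 0 and closure != "naive":
        raise ValueError("the Auger (k9 > 0) extension is built on the naive closure")
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be 1-D and strictly increasing")
    if rtol <= 0 or atol <= 0:
        raise ValueError("tolerances must be > 0")
    y0 = _initial_vector(closure, ext, init)

    if closure == "naive":
        if ext is None:
            f = lambda t, y: rhs_naive(y, rates)
        elif k9 > 0:
            f = lambda t, y: rhs_auger(y, rates, ext)
        else:
            f = lambda t, y: rhs_antibody(y, rates, ext, "naive")
    else:
        def f(t, y, _r=rates, _e=ext):
            mX, u, v, mY, mZ = y[:5]
            dmX = -_r.k1 * mX * u
            du = _r.k2 + _r.k3 * v - _r.k4 * u
            dv = _r.k5 * u - _r.k6 * v
            dmY = _r.k2 * mX + _r.k3 * mZ - _r.k4 * mY
            dmZ = _r.k5 * mY - _r.k6 * mZ
            if _e is None:
                return np.array([dmX, du, dv, dmY, dmZ])
            exch = _e.k8 * _e.tat0 * mZ - _e.k7 * y[5]
            dv += -_e.k8 * _e.tat0 * v + _e.k7 * y[5]
            return np.array([dmX, du, dv, dmY, dmZ - exch, exch])

    res = solve_ivp(f, (grid[0], grid[-1]), y0, t_eval=grid, method=method,
                    rtol=rtol, atol=atol)
    if not res.success:
        raise RuntimeError(f"ODE integration failed: {res.message}")
    diag = {"closure": closure, "method": method, "rtol": rtol, "atol": atol,
            "n_steps": int(res.t.size), "nfev": int(res.nfev)}

    if closure == "naive":
        mX, mY, mZ = res.y[0], res.y[1], res.y[2]
        mQ = res.y[3] if ext is not None else np.zeros_like(mX)
        return OdeSolution(grid, mX, mY, mZ, mQ, closure=closure, diagnostics=diag)

    mX, u, v, mY, mZ = res.y[:5]
    mQ = res.y[5] if ext is not None else np.zeros_like(mX)
    q = 1.0 - mX
    live = q > _BRANCH_EPS
    w = np.where(live, (mY - mX * u) / np.where(live, q, 1.0), u)
    s = np.where(live, (mZ - mX * v) / np.where(live, q, 1.0), v)
    return OdeSolution(grid, mX, mY, mZ, mQ, u=u, v=v, w=w, s=s,
                       closure=closure, diagnostics=diag)


def persistence_auc(sol: OdeSolution, n_dsb0: int = 160, t_end: float = 24.0) -> float:
    """Damage persistence: ``n_dsb0 * integral_0^t_end mX dt`` (DSB * hours).

    Trapezoidal quadrature on the solution grid, with the endpoint value
    interpolated if ``t_end`` falls between grid points.
    """
    if t_end > sol.t[-1] + 1e-12 or t_end < sol.t[0]:
        raise ValueError(f"t_end={t_end} outside solution span [{sol.t[0]}, {sol.t[-1]}]")
    mask = sol.t <= t_end
    t = sol.t[mask]
    x = sol.mX[mask]
    if t[-1] < t_end:
        t = np.append(t, t_end)
        x = np.append(x, np.interp(t_end, sol.t, sol.mX))
    return float(n_dsb0 * np.trapezoid(x, t))
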