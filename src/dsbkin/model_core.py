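"""State space, parameters and event propensities of the single-site DSB repair network.

The model tracks one site of DNA damage with four integer coordinates:

* ``X`` — telegraph damage indicator (1: a double-strand break is present,
  0: the site is repaired);
* ``Y`` — number of bound, activated diffusible repair molecules at the site
  (referred to as pATM, but standing for any diffusible species required for
  repair);
* ``Z`` — number of phosphorylated H2AX (gammaH2AX) molecules at the site;
* ``Q`` — number of gammaH2AX molecules sequestered by an anti-gammaH2AX-TAT
  antibody (extension only; the bound complex is inert).

Seven elementary events act on this state.  With rate constants ``k1..k6``
(all per hour) and, when the antibody extension is active, ``k7`` (antibody
dissociation, h^-1) and ``k8`` (binding, h^-1 per ug/ml of antibody):

========  ==========================  =========================
event     propensity                  state change
========  ==========================  =========================
repair    ``k1 * Y * X``              ``X -> 0``
recruit   ``k2 * X + k3 * Z``         ``Y -> Y + 1``
dissoc    ``k4 * Y``                  ``Y -> Y - 1``
phos      ``k5 * Y``                  ``Z -> Z + 1``
dephos    ``k6 * Z``                  ``Z -> Z - 1``
bind      ``k8 * [TAT]0 * Z``         ``(Z, Q) -> (Z - 1, Q + 1)``
unbind    ``k7 * Q``                  ``(Z, Q) -> (Z + 1, Q - 1)``
========  ==========================  =========================

Repair requires bound repair molecules (the propensity carries a factor
``Y``) and an existing break (factor ``X``); gammaH2AX-driven recruitment
(``k3 * Z``) continues after repair while direct recruitment (``k2 * X``)
stops.  Dephosphorylation acts on free ``Z`` only — antibody-bound ``Q`` is
inert and contributes to no propensity except unbinding.  Unphosphorylated
H2AX is abundant, so molecule counts are unbounded non-negative integers
with no pool depletion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from enum import IntEnum
from typing import Optional

import numpy as np

__all__ = [
    "RateConstants",
    "ExtensionRates",
    "SiteState",
    "AssumedConstants",
    "Event",
    "MCF7",
    "MDA_MB_468",
    "propensities",
    "apply_event",
    "stability_check",
]


class Event(IntEnum):
    """Elementary events of the single-site jump process."""

    REPAIR = 0
    RECRUIT = 1
    DISSOCIATE = 2
    PHOSPHORYLATE = 3
    DEPHOSPHORYLATE = 4
    BIND = 5
    UNBIND = 6


@dataclass(frozen=True)
class RateConstants:
    """The six core rate constants of the repair network (all h^-1).

    Parameters
    ----------
    k1
        Repair rate per bound repair (pATM) molecule.
    k2
        DSB-driven pATM recruitment rate.
    k3
        gammaH2AX-driven pATM recruitment rate, per gammaH2AX molecule.
    k4
        pATM dissociation rate, per molecule.
    k5
        H2AX phosphorylation rate, per pATM molecule.
    k6
        gammaH2AX dephosphorylation rate, per molecule.
    """

    k1: float
    k2: float
    k3: float
    k4: float
    k5: float
    k6: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"rate constant {f.name} must be finite and >= 0, got {v!r}")

    def as_dict(self) -> dict:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    def replace(self, **kw) -> "RateConstants":
        return replace(self, **kw)


@dataclass(frozen=True)
class ExtensionRates:
    """Parameters of the antibody and Auger extensions.

    Parameters
    ----------
    k7
        Antibody–gammaH2AX dissociation rate (h^-1).
    k8
        Antibody binding rate per unit antibody concentration
        (h^-1 (ug/ml)^-1).
    tat0
        Anti-gammaH2AX-TAT concentration [TAT]0 (ug/ml).
    k9
        De novo DSB induction rate per bound antibody molecule (h^-1).
        Derived as ``kappa * R`` when a specific activity ``R`` is supplied.
    kappa
        Proportionality constant in ``k9 = kappa * R`` (h^-1 per MBq/ug).
    R
        Specific activity of the 111In label (MBq/ug).
    """

    k7: float = 0.0
    k8: float = 0.0
    tat0: float = 0.0
    k9: Optional[float] = None
    kappa: float = 0.0
    R: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k7", "k8", "tat0", "kappa", "R"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"extension parameter {name} must be finite and >= 0, got {v!r}")
        if self.k9 is None:
            object.__setattr__(self, "k9", self.kappa * self.R)
        elif self.k9 < 0 or not np.isfinite(self.k9):
            raise ValueError(f"k9 must be finite and >= 0, got {self.k9!r}")
        elif self.R > 0 and not np.isclose(self.k9, self.kappa * self.R):
            raise ValueError(
                f"inconsistent Auger rates: k9={self.k9} but kappa*R={self.kappa * self.R}"
            )

    def as_dict(self) -> dict:
        return {
            "k7": float(self.k7),
            "k8": float(self.k8),
            "tat0": float(self.tat0),
            "k9": float(self.k9),
            "kappa": float(self.kappa),
            "R": float(self.R),
        }

    def replace(self, **kw) -> "ExtensionRates":
        if "R" in kw or "kappa" in kw:
            kw.setdefault("k9", None)  # re-derive from kappa * R
        return replace(self, **kw)


@dataclass(frozen=True)
class SiteState:
    """Integer state (X, Y, Z, Q) of one DNA damage site."""

    X: int = 1
    Y: int = 0
    Z: int = 0
    Q: int = 0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v != int(v) or v < 0:
                raise ValueError(f"{f.name} must be a non-negative integer, got {v!r}")
        if self.X not in (0, 1):
            raise ValueError(f"X is a telegraph signal and must be 0 or 1, got {self.X}")

    def as_tuple(self) -> tuple:
        return (self.X, self.Y, self.Z, self.Q)


@dataclass(frozen=True)
class AssumedConstants:
    """A priori molecule-count assumptions linking the model to foci data.

    ``Ymax`` — maximum bound pATM per DSB; ``Zmax`` — gammaH2AX molecules
    making up one focus; ``Zstar`` — molecules needed for a focus to be
    detectable under the microscope; ``dsb_per_gy`` — initial DSBs per cell
    per Gy of ionizing radiation.
    """

    Ymax: float = 300.0
    Zmax: float = 1000.0
    Zstar: float = 200.0
    dsb_per_gy: float = 40.0

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be > 0")
        if not self.Zstar < self.Zmax:
            raise ValueError("detection threshold Zstar must be below the focus size Zmax")

    def as_dict(self) -> dict:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}


#: Fitted rate constants for the MCF7 breast cancer cell line (h^-1).
MCF7 = RateConstants(k1=0.02, k2=1236.0, k3=20.0, k4=87.0, k5=1765.0, k6=565.0)

#: Fitted rate constants for the MDA-MB-468 breast cancer cell line (h^-1).
MDA_MB_468 = RateConstants(k1=0.0032, k2=159.0, k3=142.0, k4=716.0, k5=1056.0, k6=211.0)


def propensities(
    state: SiteState,
    rates: RateConstants,
    ext: Optional[ExtensionRates] = None,
) -> np.ndarray:
    """Event-rate vector of the jump process at ``state``.

    Returns a length-7 array indexed by :class:`Event`.  The bind/unbind
    entries are zero unless ``ext`` is given.  Antibody-bound ``Q`` is inert:
    it appears in no propensity except unbinding.
    """
    X, Y, Z, Q = state.as_tuple()
    a = np.zeros(len(Event))
    a[Event.REPAIR] = rates.k1 * Y * X
    a[Event.RECRUIT] = rates.k2 * X + rates.k3 * Z
    a[Event.DISSOCIATE] = rates.k4 * Y
    a[Event.PHOSPHORYLATE] = rates.k5 * Y
    a[Event.DEPHOSPHORYLATE] = rates.k6 * Z
    if ext is not None:
        a[Event.BIND] = ext.k8 * ext.tat0 * Z
        a[Event.UNBIND] = ext.k7 * Q
    return a


# state increments (dX, dY, dZ, dQ) per event; repair is handled separately
# because it sets X to 0 rather than decrementing it.
_STOICHIOMETRY = {
    Event.REPAIR: (0, 0, 0, 0),
    Event.RECRUIT: (0, 1, 0, 0),
    Event.DISSOCIATE: (0, -1, 0, 0),
    Event.PHOSPHORYLATE: (0, 0, 1, 0),
    Event.DEPHOSPHORYLATE: (0, 0, -1, 0),
    Event.BIND: (0, 0, -1, 1),
    Event.UNBIND: (0, 0, 1, -1),
}


def apply_event(state: SiteState, event: Event) -> SiteState:
    """Apply one elementary event, returning the new site state.

    Raises
    ------
    ValueError
        If the event would drive a count negative (its propensity at
        ``state`` is zero).
    """
    event = Event(event)
    if event is Event.REPAIR:
        if state.X != 1:
            raise ValueError("repair event at an undamaged site")
        return replace(state, X=0)
    dX, dY, dZ, dQ = _STOICHIOMETRY[event]
    new = (state.X + dX, state.Y + dY, state.Z + dZ, state.Q + dQ)
    if min(new) < 0:
        raise ValueError(f"event {event.name} would drive a count negative from {state}")
    return SiteState(*new)


def stability_check(rates: RateConstants) -> tuple[bool, float]:
    """Whether the post-repair (X=0) subsystem decays to zero.

    After repair the (Y, Z) dynamics are linear with generator
    ``[[-k4, k3], [k5, -k6]]``; both eigenvalues are negative — so pATM and
    gammaH2AX relax to the empty steady state — precisely when
    ``k3 * k5 < k4 * k6``.  Returns the boolean together with the margin
    ``k4 * k6 - k3 * k5`` (positive means stable).
    """
    margin = rates.k4 * rates.k6 - rates.k3 * rates.k5
    return margin > 0, margin
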