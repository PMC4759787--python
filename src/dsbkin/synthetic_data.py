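"""Synthetic foci/DSB time-series with the structure of the irradiation assays.

Emulates the experimental design the model was built for: cells receive a
4 Gy dose of ionizing radiation (~40 DSBs per cell per Gy, so ~160 initial
breaks per cell), and the mean DSB count (chi1, comet-assay channel) and
mean gammaH2AX focus count (chi2, immunofluorescence channel) are sampled
over 0-24 h, optionally under antibody ([TAT]0) and 111In (R) conditions.

chi1 is emitted directly in DSB-count units: the experimental Olive tail
moment is an arbitrary-unit proxy for the same quantity, and the
calibration layer between the two is outside this package's scope.

Noise model: multiplicative Gaussian with a per-channel coefficient of
variation (foci counts are averages over many cells, so continuous noise
is adequate), clamped at zero; optional Poisson cell-count thinning adds
per-cell counting noise.

Each observation set carries a model-consistent no-H2AX reference channel
``chi1_bar`` (the k5 = 0 barred solution mapped to DSB counts), so that
noiseless curves (CV = 0) round-trip through the fitting objective to zero
at the generating parameters; fits of real-style data lacking the channel
fall back to the time-dilation construction in :mod:`dsbkin.fitting`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml

from .fitting import TimeSeriesObservations, foci_from_model
from .model_core import AssumedConstants, ExtensionRates, RateConstants
from .moment_odes import integrate
from .ssa import ensemble

__all__ = ["ExperimentDesign", "generate_observations", "generate_antibody_panel",
           "write_manifest"]

_DEFAULT_TIMES = (0.0, 0.5, 1.0, 2.0, 4.0, 6.0, 24.0)


@dataclass(frozen=True)
class ExperimentDesign:
    """Design of one synthetic irradiation experiment.

    ``conditions`` lists (tat0, R) pairs, one observation set per pair;
    ``cv`` is the multiplicative-noise coefficient of variation per channel;
    ``cells_per_measurement`` switches on Poisson counting noise (counts
    summed over that many cells, then averaged).
    """

    dose_gy: float = 4.0
    dsb_per_gy: float = 40.0
    times: Sequence[float] = _DEFAULT_TIMES
    conditions: Sequence[tuple[float, float]] = ((0.0, 0.0),)
    cv: float = 0.1
    cells_per_measurement: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dose_gy < 0 or self.cv < 0 or self.dsb_per_gy < 0:
            raise ValueError("dose, dsb_per_gy and cv must be >= 0")
        t = np.asarray(self.times, dtype=float)
        if np.any(np.diff(t) <= 0) or np.any(t < 0):
            raise ValueError("sample times must be sorted, distinct and non-negative")

    @property
    def n_dsb0(self) -> int:
        return int(round(self.dose_gy * self.dsb_per_gy))


def _noisify(values: np.ndarray, design: ExperimentDesign, rng: np.random.Generator):
    out = np.asarray(values, dtype=float).copy()
    if design.cells_per_measurement:
        n = design.cells_per_measurement
        out = rng.poisson(np.maximum(out, 0.0) * n) / n
    if design.cv > 0:
        out = out * (1.0 + design.cv * rng.standard_normal(out.shape))
    return np.maximum(out, 0.0)


def _model_curves(rates, ext, design, generator, closure, constants, n_reps, sub_seed):
    grid = np.asarray(design.times, dtype=float)
    prepend = grid[0] != 0.0
    if prepend:
        grid = np.concatenate(([0.0], grid))
    if generator == "ode":
        use_closure = "naive" if (ext is not None and ext.k9 > 0) else closure
        sol = integrate(use_closure, rates, ext=ext, grid=grid if grid.size > 1
                        else np.array([0.0, 1e-3]))
        mX, mZ, mQ = sol.mX, sol.mZ, sol.mQ
        if grid.size == 1:
            mX, mZ, mQ = mX[:1], mZ[:1], mQ[:1]
    elif generator == "ssa":
        summ = ensemble(rates, ext=ext, grid=grid, n_reps=n_reps, seed=sub_seed)
        mX, mZ, mQ = summ.mean_X, summ.mean_Z, summ.mean_Q
    else:
        raise ValueError(f"unknown generator {generator!r}")
    if prepend:
        mX, mZ, mQ = mX[1:], mZ[1:], mQ[1:]
    return mX, mZ, mQ


def generate_observations(
    truth: RateConstants,
    design: ExperimentDesign = ExperimentDesign(),
    ext: Optional[ExtensionRates] = None,
    generator: str = "ode",
    closure: str = "conditional",
    constants: AssumedConstants = AssumedConstants(),
    count_bound: bool = True,
    n_reps: int = 1000,
) -> list[TimeSeriesObservations]:
    """Simulate the design, one observation set per (tat0, R) condition.

    The model curves come from the chosen closure (``generator="ode"``) or
    from an SSA ensemble of ``n_reps`` replicates (``generator="ssa"``);
    they are mapped to (chi1, chi2) via ``n_dsb0 * mX`` and the foci map,
    then passed through the noise model.  Deterministic for a given
    ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    ssa_seeds = np.random.SeedSequence(design.seed).generate_state(len(design.conditions))
    grid = np.asarray(design.times, dtype=float)
    bar_grid = grid if grid[0] == 0.0 else np.concatenate(([0.0], grid))
    bar_sol = integrate("naive", truth.replace(k5=0.0),
                        grid=bar_grid if bar_grid.size > 1 else np.array([0.0, 1e-3]))
    bar_mX = bar_sol.mX if grid[0] == 0.0 else bar_sol.mX[1:]
    bar_mX = bar_mX[: grid.size]
    out = []
    for i, (tat0, R) in enumerate(design.conditions):
        cond_ext = ext
        if tat0 > 0 or R > 0:
            base = ext if ext is not None else ExtensionRates(k7=1.0, k8=10.0)
            cond_ext = base.replace(tat0=tat0, R=R)
        elif ext is not None:
            cond_ext = ext.replace(tat0=0.0, R=0.0)
        mX, mZ, mQ = _model_curves(truth, cond_ext, design, generator, closure,
                                   constants, n_reps, int(ssa_seeds[i]))
        mZ_total = mZ + (mQ if count_bound else 0.0)
        chi1 = design.n_dsb0 * np.asarray(mX)
        chi2 = foci_from_model(mZ_total, design.n_dsb0, constants.Zmax)
        out.append(
            TimeSeriesObservations(
                t=np.asarray(design.times, dtype=float),
                chi1=_noisify(chi1, design, rng),
                chi2=_noisify(chi2, design, rng),
                chi1_bar=_noisify(design.n_dsb0 * bar_mX, design, rng),
                tat0=float(tat0),
                R=float(R),
            )
        )
    return out


def generate_antibody_panel(
    truth: RateConstants,
    tat0_list: Sequence[float] = (0.0, 0.025, 0.05, 0.5),
    design: ExperimentDesign = ExperimentDesign(),
    ext: Optional[ExtensionRates] = None,
    **kw,
) -> list[TimeSeriesObservations]:
    """Observation sets across anti-gammaH2AX-TAT concentrations (ug/ml).

    The default concentrations are the experimentally used panel
    {0, 0.025, 0.05, 0.5} ug/ml.
    """
    from dataclasses import replace as _replace

    design = _replace(design, conditions=tuple((c, 0.0) for c in tat0_list))
    return generate_observations(truth, design, ext=ext, **kw)


def write_manifest(
    path,
    truth: RateConstants,
    design: ExperimentDesign,
    ext: Optional[ExtensionRates] = None,
    constants: AssumedConstants = AssumedConstants(),
    extra: Optional[dict] = None,
) -> None:
    """Record truth parameters, design and seeds as YAML beside a data set,
    so parameter-recovery experiments are self-describing."""
    doc = {
        "truth": truth.as_dict(),
        "extension": ext.as_dict() if ext is not None else None,
        "constants": constants.as_dict(),
        "design": {
            "dose_gy": design.dose_gy,
            "dsb_per_gy": design.dsb_per_gy,
            "times": [float(t) for t in design.times],
            "conditions": [list(map(float, c)) for c in design.conditions],
            "cv": design.cv,
            "cells_per_measurement": design.cells_per_measurement,
            "seed": design.seed,
        },
    }
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
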