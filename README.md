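# dsbkin

Stochastic and mean-field modelling of DNA double-strand-break (DSB)
repair kinetics, observed through γH2AX foci.

## Who this is for

Radiobiologists and modellers who quantify DSB repair from per-cell time
series — mean DSB counts (comet assay) and mean γH2AX focus counts
(immunofluorescence) — and who want a mechanistic, fittable link between
molecular events at individual damage sites and those population-scale
measurements, including perturbations by an anti-γH2AX-TAT antibody and by
¹¹¹In Auger-electron irradiation delivered through it.

## The model

One damage site carries an integer state (X, Y, Z, Q):

* `X ∈ {0,1}` — telegraph damage signal (1: a DSB is present),
* `Y` — bound, activated diffusible repair molecules (pATM as a proxy),
* `Z` — phosphorylated H2AX (γH2AX) molecules,
* `Q` — antibody-bound γH2AX (extension only; the complex is inert).

Events and propensities (all rates h⁻¹):

| event | propensity | change |
|---|---|---|
| repair | k₁·Y·X | X→0 |
| recruitment | k₂·X + k₃·Z | Y→Y+1 |
| dissociation | k₄·Y | Y→Y−1 |
| phosphorylation | k₅·Y | Z→Z+1 |
| dephosphorylation | k₆·Z | Z→Z−1 |
| antibody binding | k₈·[TAT]₀·Z | (Z,Q)→(Z−1,Q+1) |
| antibody unbinding | k₇·Q | (Z,Q)→(Z+1,Q−1) |

The package provides

* exact Gillespie simulation of this jump process (`dsbkin.ssa`), single
  site or whole populations, plus detectable-foci thresholding
  (a focus is visible when Z ≥ Z\* = 200);
* two moment-closure ODE reductions of the master equation
  (`dsbkin.moment_odes`): the independence closure
  `d⟨X⟩/dt = −k₁⟨X⟩⟨Y⟩` and the conditional-mean closure built on
  u = E[Y|X=1] etc., with antibody (d⟨Q⟩/dt = k₈[TAT]₀⟨Z⟩ − k₇⟨Q⟩) and
  Auger (d⟨X⟩/dt += k₉⟨Q⟩(1−⟨X⟩), k₉ = κR) extensions and the damage
  persistence integral AUC = N₀∫⟨X⟩dt;
* the observation maps and least-squares Nelder–Mead fitting of k₁…k₆ to
  (χ₁, χ₂) series (`dsbkin.fitting`), with foci = N₀·⟨Z⟩/Z_max
  (Z_max = 1000 molecules per focus) and a ~10× time-dilated no-H2AX
  reference channel, plus per-concentration fitting of the antibody
  grouping g = k₈[TAT]₀/k₇;
* a synthetic-experiment generator emulating a 4 Gy irradiation
  (≈40 DSB/cell/Gy ⇒ 160 initial breaks) sampled over 0–24 h with
  multiplicative measurement noise (`dsbkin.synthetic_data`);
* YAML/CSV/JSON I/O and a `dsbkin` command line (`dsbkin.cli_io`).

Fitted rate constants for two breast-cancer cell lines ship as fixtures
(`dsbkin.MCF7`, `dsbkin.MDA_MB_468`).

## Worked example

```python
import numpy as np
import dsbkin as dk

# deterministic mean behaviour after 4 Gy (160 initial DSBs), MCF7 rates
sol = dk.integrate("conditional", dk.MCF7, grid=np.linspace(0, 24, 25))
for t in (0, 1, 2, 4):
    i = list(sol.t).index(t)
    print(f"t={t:2d} h  DSBs/cell={160*sol.mX[i]:7.2f}  "
          f"foci/cell={dk.foci_from_model(sol.mZ, 160)[i]:6.2f}")

# stochastic check: 1000 Gillespie replicates
summ = dk.ensemble(dk.MCF7, grid=np.linspace(0, 24, 25), n_reps=1000, seed=17)
print(f"SSA mean DSBs at 1 h: {160*summ.mean_X[1]:.2f} "
      f"(+/- {160*summ.se_X[1]:.2f})")
```

prints

```
t= 0 h  DSBs/cell= 160.00  foci/cell=  0.00
t= 1 h  DSBs/cell=  61.12  foci/cell= 10.10
t= 2 h  DSBs/cell=  22.30  foci/cell=  3.69
t= 4 h  DSBs/cell=   2.97  foci/cell=  0.49
```

```
SSA mean DSBs at 1 h: 60.80 (+/- 2.46)
```

Half of the initial damage is repaired within ~0.7 h; the focus count
peaks below 17 per cell (between the 0.5 h and 1 h samples) because each
focus is only scored as Z_max = 1000 molecules' worth of γH2AX, and the
stochastic ensemble agrees with the ODE mean within Monte-Carlo error.

The same model fits back its own synthetic data:

```python
obs = dk.generate_observations(dk.MCF7, dk.ExperimentDesign(cv=0.0, seed=1))[0]
guess = dk.RateConstants(**{k: 0.5 * v for k, v in dk.MCF7.as_dict().items()})
fit = dk.fit_baseline(obs, init_guess=guess, seed=1)
print(fit.rates)   # recovers k1=0.02, k2=1236, ... exactly (objective ~1e-13)
```

Command-line equivalents: `dsbkin solve`, `dsbkin simulate`, `dsbkin fit`,
`dsbkin fit-antibody`, `dsbkin auger-scan`, `dsbkin generate`,
`dsbkin report` (see `--help`).

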