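# rotorflim

Viscosity imaging with fluorescent molecular rotors (FMRs) and fluorescence
lifetime imaging microscopy (FLIM), as one tested pipeline: TCSPC decay
simulation and reconvolution fitting, Förster-Hoffman lifetime-viscosity
calibration, per-pixel viscosity maps, colocalisation metrics, Welch
statistics — plus the molecular-dynamics observables (lateral MSD, C-H
order parameters, first-shell hydration) used to verify that a
membrane-embedded rotor does not perturb the bilayer it probes.

## Who this is for

An FMR is a dye whose excited state can rotate around a single bond; the
rotation opens a non-radiative decay channel, so in a viscous medium —
where rotation is hindered — the fluorescence lifetime grows. Imaging the
lifetime pixel by pixel (FLIM) therefore maps viscosity, with applications
from organelle biophysics to drug delivery. This package is for
experimentalists who have TCSPC decays, FLIM cubes or co-staining images
to analyse, and for simulators who want the standard bilayer observables
computed from trajectories — with every stage testable on synthetic data
of known ground truth.

## The models at the core

**Reconvolution decay fitting.** A measured TCSPC histogram is modelled as

    m(t) = offset + IRF(t - shift) * Σᵢ aᵢ exp(-t/τᵢ)

(`*` is convolution; up to three components; one period of incomplete-decay
wrap-around is included). Amplitudes and offset enter linearly and are
solved by non-negative least squares inside a trust-region search over
(lifetimes, IRF shift); a Poisson maximum-likelihood polish — the correct
objective at FLIM's low photon counts — refines all parameters. Standard
errors come from the curvature at the optimum.

**Förster-Hoffman calibration.** A rotor obeys the empirical power law
τ = z·η^α, a straight line in log-log space. BODIPY rotors typically show
two regimes, so the calibration is a continuous two-segment power law; the
breakpoint is found by exhaustive search plus continuous refinement, and
continuity makes the lifetime→viscosity inversion single-valued.

**Bilayer observables.** Lateral mean square displacement
MSD(t) = ⟨Δx² + Δy²⟩ (slope 4D for free 2-D diffusion); the
carbon-hydrogen order parameter S_CD = (3⟨cos²β⟩ − 1)/2 with β the C-H
angle to the bilayer normal, grouped by leaflet and lateral distance to
the probe (bins 0.7 / 1.0 / 1.6 / 2.0 nm); and first-shell water counts
around the onium, phosphate and ester groups, with shell cutoffs taken
from the first minimum after the first peak of the corresponding radial
distribution function.

## Worked example

Simulate a control-condition decay (mono-exponential, 2473 ps, 90 ps
Gaussian IRF, 10⁵ photons), fit it, and convert the lifetime to a matrix
viscosity through an anchored calibration:

```python
from rotorflim.synthetic import DecaySpec, generate_decay
from rotorflim.tcspc import fit_decay
from rotorflim.calibration import anchor_curve

spec = DecaySpec(lifetimes_ps=(2473.0,), total_counts=1e5, seed=1)
res = fit_decay(generate_decay(spec), spec.build_irf())
print(res.summary())

curve = anchor_curve((274.7, 2473.0), 0.63)   # (cP, ps) anchor, exponent
print(f"treated 2967 ps -> {curve.lifetime_to_viscosity(2967.0):.1f} cP")
```

prints

```
Reconvolution fit: 1 component(s), objective=poisson
converged: True   reduced chi-square: 0.4773
  tau_1 =    2468.6 +/-     8.1 ps   a_1 = 7929 +/- 36.3
  offset = 0 +/- 0.000301 counts/ch   IRF shift = 1.3 +/- 2.3 ps
  mean lifetime (amplitude-weighted) = 2468.6 ps
treated 2967 ps -> 366.8 cP
```

The fitted lifetime recovers the generating 2473 ps within its ~8 ps
standard error, and inverting the anchored power law at the treated
condition's 2967 ps gives 366.8 ≈ 367 cP. Fitting a full two-segment
calibration works the same way from a (viscosity, lifetime) table:

```python
from rotorflim.synthetic import generate_calibration_set
from rotorflim.calibration import ForsterHoffmanModel

points = generate_calibration_set(relative_noise=0.05, seed=1).points
print(ForsterHoffmanModel(points).fit(n_segments=2).summary())
```

```
Forster-Hoffman calibration, 2 segment(s), 16 points
  low-viscosity gradient alpha = 0.2490, log10 z = 2.3616
  high-viscosity gradient alpha = 0.6270, log10 z = 1.7353
  breakpoint eta* = 45.4 cP (tau* = 595 ps)
  validity range: 0.6 - 1.18e+03 cP
  log10 residual RMSE = 0.0128
```

recovering the generating gradients 0.25 / 0.63 from 5%-noisy lifetimes.

A `rotorflim` command-line tool wraps the same operations
(`fit-decay`, `fit-flim`, `calibrate`, `convert`, `coloc`,
`map-viscosity`, `object-stats`, `md-msd`, `md-scd`, `md-hydration`,
`welch`, `run` for configured multi-stage pipelines).

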