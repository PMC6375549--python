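# Methods

This note records the models implemented in `rotorflim`, the defaults and
why they were chosen, the numerical choices that affect results, and what
the synthetic-data tests do and do not demonstrate about real data.

## TCSPC decay model and fitting

A TCSPC histogram of `n` channels of width Δt over window `T` is modelled
as the discrete convolution of a multi-exponential decay with the
instrument response function (IRF), plus a constant offset:

    m_k = offset + Σ_i a_i · (IRF_shift ⊛ d_i)_k,
    d_i(t) = exp(-t/τ_i) · (1 + exp(-T/τ_i))

The second factor adds the photons excited by the *previous* laser pulse
(incomplete-decay wrap-around). At a 20 MHz repetition rate the 50 ns
window equals the repetition period, so one preceding period captures
essentially all the wrap (for τ = 4.6 ns, the two-period term is
exp(-2T/τ) ≈ 10⁻⁹ of the peak). Bin centres `(k+½)Δt` sample the decay.

Fitting proceeds in two stages:

1. **Variable projection.** For fixed (τ's, IRF shift) the amplitudes and
   offset are linear and solved by non-negative least squares under Neyman
   weights `1/√max(y,1)`. The outer problem over (log τ's, shift) is
   solved with `scipy.optimize.least_squares` (trust-region reflective,
   `x_scale='jac'`, up to 3000 evaluations — the evaluation budget matters:
   with the scipy default the optimiser stalls far from the optimum on
   3-component problems).
2. **Poisson maximum-likelihood polish** (default objective) over all
   parameters with L-BFGS-B. Poisson MLE is the statistically correct
   objective at FLIM's low counts; Neyman-weighted least squares is kept
   as an option for comparability with conventional software. The polish
   never replaces the stage-1 solution with a worse one; a line-search
   failure at an already-converged point does not clear the convergence
   flag.

Standard errors are delta-method transforms of the inverse
finite-difference Hessian at the optimum. Reduced chi-square uses Neyman
weights and `n - (2k + 2)` degrees of freedom. Components are sorted
ascending by lifetime; lifetimes closer than 5% trigger a degeneracy
warning. Non-convergence and empty histograms are flagged on the result,
never raised.

Parameters that matter:

| parameter | default | unit | rationale |
|---|---|---|---|
| `n_channels` | 256 | — | typical TCSPC ADC resolution; 1024 resolves sub-channel lifetimes better |
| `window_ps` | 50 000 | ps | 20 MHz repetition rate |
| IRF FWHM | 90 | ps | pulsed diode laser pulse width |
| IRF centre | 5% of window | ps | leaves the rising edge fully sampled |
| IRF shift bound | ±5 channels | — | no alignment procedure is assumed; the shift is fitted |
| `count_threshold` (FLIM) | 100 | counts | below ~100 photons a mono-exponential fit is unreliable |
| `spatial_binning` | 1 | px | sliding-window sum (image size preserved), as in common FLIM software |

Known numerical caveat: the unit floor in the Neyman weights makes
weighted-LS fits invariant to uniform intensity rescaling only to ~1%
(the floor's relative weight changes with scale); without a floor, empty
channels would get infinite weight.

Mean lifetimes are amplitude-weighted by default (Σaτ/Σa), the common
reporting convention; intensity weighting (Σaτ²/Σaτ) is a flag. Per-cell
lifetimes can be taken either as the fit to the cell-summed decay
(default: uses all photons at once) or the mean of per-pixel lifetimes.

## Förster-Hoffman calibration

Lifetime and viscosity follow τ = z·η^α piecewise: two segments in log-log
space joined continuously at a breakpoint η*. Continuity is imposed —
without it the inversion τ→η can be multi-valued. The fit is ordinary
least squares in (log₁₀η, log₁₀τ) with a hinge basis; the breakpoint is
chosen by exhaustive search over interior data positions and gap
midpoints (each segment keeps ≥3 points), then refined continuously
inside the winning gap (`minimize_scalar`, bounded). On noiseless
two-slope data this recovers the gradients to ~10⁻⁸ and the breakpoint to
optimizer tolerance.

Inversion selects the segment by comparing τ with τ(η*); conversions
outside the calibrated viscosity range are allowed but flagged as
extrapolations. Temperature/polarity/ionic-strength control measurements
are ordinary labelled calibration points — the rotor responds to
viscosity only, so they need no separate model.

Relative quantum yields use the standard two-cuvette formula
QY = QY_ref · (n²/n_ref²) · (I/Abs) · (Abs_ref/I_ref); absorbances outside
the 0.02-0.05 linear band warn. A PM546-in-methanol reference preset
(QY 0.95, n 1.3292) is packaged.

## Image metrics

Pearson r is the plain product-moment correlation over masked pixels;
`colocalise` masks to the union of above-threshold pixels so empty
background does not inflate r. Manders M1 is the fraction of channel-1
intensity in pixels where channel 2 exceeds its threshold (M2
symmetrically); thresholds default to 0 (the classic coefficients), with
Otsu thresholds available. Segmentation is Otsu-or-fixed thresholding
plus connected-component labelling with a minimum size; per-object tables
report mean, population SD and pixel count, and condition summaries treat
each object (cell) as one observation — per-object means are *not*
pixel-pooled, so large objects do not dominate.

Viscosity maps apply the calibration inversion pixelwise; masked pixels
stay NaN and extrapolated pixels are flagged, never silently filled.

## Trajectory observables

All distances are minimum-image in an orthorhombic box; the bilayer
normal is fixed to the box z axis (standard for planar bilayers; no
instantaneous-surface fitting). Lateral MSD averages squared x-y
displacements over atoms and over reference frames spaced by
`origin_stride` (default every 10th frame; a single-origin mode matches
the textbook single-`t_ref` definition). MSD requires unwrapped
coordinates; `unwrap` accumulates minimum-image increments and warns when
an inter-frame displacement approaches half the box (undersampled
frames make unwrapping ambiguous). The diffusion fit uses the first
quarter of lags, where origin averaging is densest.

S_CD is computed per C-H bond against +z, averaged first over a carbon's
hydrogens, then over (lipid, frame) samples within each group. With a
probe present, lipids are assigned each frame (dynamic assignment — a
lipid may change bins over time) to one of five lateral-distance bins
(edges 0.7/1.0/1.6/2.0 nm, closed left/open right) using the
phosphorus-to-probe x-y distance, and to the same/opposite leaflet by the
sign of the phosphorus z relative to the mean-phosphorus midplane.

RDFs are shell-volume-normalised pair densities; the first-shell cutoff
is the first local minimum after the first peak of g(r), after an
optional 3-bin moving average; monotone profiles yield no cutoff and are
flagged. Hydration counts water oxygens within the group cutoff of *any*
atom of the group — a union, which matters for the two ester oxygens (a
water near both is one neighbour, not two). Counts are averaged over
frames and over lipids per (group, leaflet, bin) cell; the output always
carries the full 3×2×5 grid, with NaN/0 for unsampled cells.

## Synthetic data: what it emulates, what it does not

The generators reproduce the *statistical structure* of each input
family: Poisson-distributed TCSPC counts under the reconvolution model;
FLIM scenes of uniform-lifetime discs (front-most object wins overlaps);
image pairs with exactly constructed object overlap; 2-D Brownian motion
with per-axis increment variance 2DΔt; grid-built bilayers whose C-H
bonds all make a prescribed angle with the normal and whose first
hydration shells are placed by construction; and calibration points on an
exact two-segment power law with multiplicative lifetime noise (default
5%). Calibration defaults span ~200 ps at 0.6 cP to ~4.6 ns at 1178 cP
with gradients 0.25/0.63 and a continuity-implied breakpoint near 45 cP.

Deliberately *not* modelled: photon pile-up, afterpulsing and dark
counts; detector IRF asymmetry (the default IRF is Gaussian — a measured
IRF histogram can be supplied instead); spatial correlations and
scattering in images; and any physically realistic membrane (the toy
bilayer has rigid geometry, no thermal disorder). Passing tests therefore
demonstrate correctness of the estimators on their assumed models, not
robustness to instrument artefacts; the low-count recovery study
(median lifetime error <15% at 300 photons) is the closest proxy for
real FLIM pixel statistics.

Every generator is a pure function of its spec and seed
(`numpy.random.default_rng`); identical inputs give bit-identical
outputs, and ground truth is always returned alongside the data.

## Problem sizes used in the validation suite

Chosen to give stable statistics: 150 mono-exponential replicates at 10⁵
counts and 50 three-component replicates at 10⁶ counts (lifetimes
500/2000/8000 ps, resolvable on the 195 ps channel grid) for decay-fit
recovery; 200 replicate calibration sets at 5% noise; 200 atoms × 5000
frames for the Einstein-relation check; 10⁴ random orientations for the
isotropic-S_CD average; 1000 seeds for the Poisson-expectation property
(with a ≤2-of-64-channels multiplicity allowance on the per-channel 3-SE
band, since one chance excursion is expected among 64 channels).

## Known limitations

- No phasor, global (image-wide shared lifetime) or Bayesian fitting.
- Pixels are fitted independently; no spatial regularisation beyond
  binning.
- The two-segment calibration assumes exactly one breakpoint; more
  regimes would need a different model-selection step.
- Leaflet assignment assumes a planar bilayer with a well-defined
  midplane; curved membranes are out of scope.
- The GRO reader handles concatenated orthorhombic-box frames (via
  mdtraj); compressed trajectory formats are not read.
- Welch tests on per-cell summaries assume the per-cell means are
  approximately normal; no non-parametric alternative is provided.
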