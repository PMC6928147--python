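# Methods

## The physical model

`csflux` models the transmembrane exchange of a monovalent cation (the
motivating system is ¹³³Cs⁺ entering human erythrocytes through
yoda1-activated Piezo1 channels) observed by NMR in two regimes:

**Hyperpolarized (dDNP) regime.** The injected ions carry a hyperpolarized
("labelled") longitudinal magnetization some 10⁴-fold above the Boltzmann
level. Because the intra- and extracellular resonances are chemically
shifted (~4 ppm, the split-peak effect), the two compartments are resolved
without shift reagents. The labelled amounts `L_o(t)`, `L_i(t)` obey

    dL_o/dt = −L_o/T₁,o + ln(cos α)·L_o/t_R − k₁·L_o + k₋₁·L_i
    dL_i/dt = −L_i/T₁,i + ln(cos α)·L_i/t_R + k₁·L_o − k₋₁·L_i

with first-order influx/efflux constants `k₁, k₋₁` (s⁻¹), longitudinal
relaxation times `T₁,o, T₁,i` (s), and the continuous approximation
`ln(cos α)/t_R` for the losses caused by an α-degree read pulse every `t_R`
seconds. Relaxation and pulse losses convert labelled ions to relaxed
("unlabelled") ones without chemical change; the unlabelled pools gain
exactly those amounts while exchanging with the same rate constants, so the
four-pool total is conserved. The four-pool system is how the package
computes total chemical flux from a label-only measurement.

**Thermal regime.** Conventional acquisition at Boltzmann polarization, a
spectrum every 10–20 s over hundreds of seconds. Polarization regenerates
between scans and each acquired pair of peak integrals is normalized to sum
to 1 (conservation of mass), so the model is pure two-site exchange of
fractions:

    d(out)/dt = −k₁·out + k₋₁·in,   out + in = 1,

approaching the equilibrium split `(k₋₁, k₁)/(k₁+k₋₁)` with rate `k₁+k₋₁`.
The relaxation and pulse-loss terms are deliberately absent from this model:
with pair-sum normalization they are unidentifiable, and retaining them
would make every trajectory decay to zero, contradicting the observed
plateaus. This was a genuinely open modelling choice and is the package's
position.

## Numerical solution

All systems are linear with constant coefficients, so propagation uses
matrix exponentials rather than a step integrator:

- the 2×2 labelled system uses a hand-derived closed form. For triangular
  cases (either rate constant zero — including the entire dDNP fitting
  path) each mode is evaluated exactly and the coupling term uses `expm1`,
  which is free of the catastrophic cancellation that a naive
  two-exponential difference suffers when the eigenvalues are far apart.
  The general case uses the uniform cosh/sinh form of the exponential,
  exact in the repeated-eigenvalue limit via a series switch;
- the 4×4 labelled+unlabelled system steps with `scipy.linalg.expm`
  between output instants (one exponential per distinct step size). Because
  the generator's columns sum to zero, conservation holds to machine
  precision (~10⁻¹⁴ observed, against a 10⁻⁹ requirement);
- `scipy.linalg.expm` applied directly (`closed_form_labelled`) serves as
  an independent oracle for the hand-derived propagator, and
  `solve_ivp`/LSODA (rtol 10⁻⁸, atol 10⁻¹⁰) cross-checks the four-pool
  path in the test suite. The stepped-exponential default was chosen over
  the integrator because exactness costs nothing for a linear system and
  the propagator sits inside MCMC loops.

**Discrete pulses.** `propagate_discrete_pulses` solves the pulse-free
equations between read pulses and multiplies both labelled pools by
`cos α` at each pulse, reporting pre-pulse amounts (the `sin α` detection
factor is absorbed into the normalization, since only relative integrals
are ever fitted). A useful exact result falls out: because the per-pulse
loss is the same scalar for both compartments, it commutes with the
exchange matrix, and at pre-pulse sampling instants the discrete model
coincides *exactly* with the `ln(cos α)/t_R` continuous approximation. The
"little difference" between the two treatments is therefore zero in this
convention, and the test suite pins the discrepancy at < 10⁻¹² (against a
1–2% documentation bound).

## Synthetic data

No raw peak-integral data accompany the experiments this package models, so
validation is by parameter recovery on generated datasets:

- **dDNP courses**: 40 samples at `t_R` = 1 s, flip angle 10°, zero-trans
  initial condition (all signal extracellular), additive i.i.d. Gaussian
  noise with the same sd on both peaks (receiver noise is
  peak-independent). Default sd = 0.005 of the initial extracellular
  integral. Negative noisy integrals are retained — clipping would bias
  the near-baseline tail. An optional flag shrinks the first extracellular
  point to mimic the incomplete-mixing artifact of the first spectrum.
- **thermal courses**: a spectrum every 20 s to 1200 s (> 3 equilibrium
  half-times at the reference constants), noise added then each pair
  renormalized to sum 1, as measured pairs are.

Reference truth values for fixtures span the experimentally observed range:
dDNP (T₁,o, T₁,i, k₁) of (8.9 s, 1.2 s, 0.0057 s⁻¹), (9.6, 3.0, 0.0024) and
(13.6, 2.4, 0.0008); thermal (k₁, k₋₁) of (0.0043, 0.0091) and
(0.0043, 0.013) s⁻¹.

What the generator does *not* emulate: spectral-domain (Rician) noise,
baseline and lineshape artifacts, drift, B₁ inhomogeneity, or cell-volume
changes. Passing recovery tests therefore demonstrate estimator
correctness under the stated noise model, not robustness to instrumental
artifacts.

## Inference

**dDNP (MCMC).** Affine-invariant ensemble sampling (emcee) of
`(T₁,o, T₁,i, k₁, amplitude, noise_sd)` in log space under independent
log-uniform priors: T₁ ∈ [0.1, 100] s, k₁ ∈ [10⁻⁵, 1] s⁻¹, amplitude ∈
[0.01, 100], sd ∈ [10⁻⁶, 1] (log-uniform = Jeffreys for a bounded scale
parameter). The efflux constant is fixed at zero: over a ~40 s course the
extent of reaction is below 1%, making `k₋₁` unidentifiable, and
simulations with the plausible `k₋₁` = 0.0121 s⁻¹ change the labelled
trajectories by less than 10⁻³ of the dose. The initial amplitude is a free
parameter rather than being pinned to the artifact-prone first point, and
`drop_first` discards that point by default. The likelihood is i.i.d.
Gaussian over both channels (optionally the extracellular channel alone,
used by the identifiability tests). Defaults: 40 walkers × 50,000 steps,
50% burn-in, a 0.8/0.2 mixture of differential-evolution and snooker moves,
walkers started in a tight ball around a least-squares point. The DE moves
and chain length are sized for the worst default-noise case, where the k₁
posterior has a diffuse log-space plateau below the detection threshold and
shorter stretch-move runs leave split-R̂ above 1.05. Split-R̂ (over
walkers) and effective sample size are computed with ArviZ for every
parameter; any R̂ above 1.05 clears the `converged` flag rather than
raising.

At the default noise level (sd 0.005) the intracellular peak is ~0.0048 of
the initial signal — per-point SNR ≈ 1 — so `k₁` is intrinsically weakly
identified from a single course: its posterior sd is of the same order as
its value, and the posterior mean sits below the generating value under the
1/k prior weight. This is a property of the experimental design at that
noise level, not of the sampler (verified against an independent
Laplace-marginalization of the likelihood); recovery is asserted as
truth-within-2-posterior-sd, and the uncertainty is reported, never
suppressed. At sd ≤ 0.001 the posterior tightens to a few percent and the
same machinery recovers all parameters sharply.

**Thermal (least squares).** `scipy.optimize.least_squares` on both
channels jointly with standard errors from `s²(JᵀJ)⁻¹`. After pair-sum
normalization the two channels are exact mirrors, so the joint fit
duplicates each observation; estimates are unaffected. Non-convergence is
flagged on the result, not raised. A test cross-checks that an independent
MCMC over the thermal likelihood peaks within one standard error of the
least-squares solution.

**Posterior predictive.** Trajectory draws from the stored chain, by
default with per-draw observation noise added, so the 95% band is a true
predictive interval against which data coverage (≥ 90% asserted over 20
seeded replicates) is meaningful; a trajectory-only band is available via
`include_noise=False`.

## Derived biophysics

- Permeability `P_d = k₋₁ · V_water/A` with erythrocyte defaults 62 fL and
  143 μm² (→ 3.9×10⁻⁷ cm s⁻¹ at k₋₁ = 0.0091 s⁻¹).
- Nernst and Goldman potentials with R = 8.314 J mol⁻¹ K⁻¹, T = 310.15 K
  and Faraday's constant 96.5 kC mol⁻¹ — the conventionally rounded value,
  kept (rather than CODATA 96485.33) so worked numbers match the standard
  printed arithmetic; the difference is 0.02%.
- Initial influx `k₁·[ion]_out/Ht` (mmol (L cells)⁻¹ s⁻¹); per-cell and
  per-channel turnover via the 86 fL isovolumic cell volume and an
  explicit channel copy number (default 55 trimers per cell, deliberately a
  parameter — the published count may be several-fold low).
- Aqueous volume fractions `Ht·0.717` and `1−Ht`; at transmembrane
  concentration equality the out:in signal ratio equals this volume ratio
  (68:32 at Ht 0.4).

All functions return full precision; rounding to reporting precision
(e.g. 1.6 million ions cell⁻¹ s⁻¹ for 1.55×10⁶) is the caller's choice.

## Problem sizes and numerical conventions

Simulation grids: 4000 points over 0–40 s for locating the intracellular
maximum; acquisition grids are the pulse times themselves. MCMC defaults
as above (~1 min per fit); the replicate calibration bank in the test
suite uses 4,000-step chains at sd 0.001, where the compact posterior
mixes quickly. Time origin is the first acquired spectrum, with an
optional injection dead-time offset (default 0). Units throughout:
seconds, s⁻¹, degrees, mM, fL, μm², cm s⁻¹, mV.

## Known limitations

- The dDNP estimator assumes the continuous-pulse likelihood by default;
  the discrete-pulse switch exists but is slower and, at pre-pulse
  sampling, numerically identical.
- No spectral simulation: the package consumes peak integrals, not FIDs.
- No concentration-dependent (saturable) rate laws; first-order constants
  only.
- No hierarchical pooling across experiments and no model comparison
  (e.g. dDNP fits with free k₋₁).
- Single-ion Goldman potential with one anion term; Donnan effects of
  impermeant polyanions are out of scope.
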