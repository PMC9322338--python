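# Methods

## The three-pool model

The simulator tracks longitudinal magnetization in the three detectable
pools of a hyperpolarized [1-¹³C]pyruvate experiment — pyruvate (P),
lactate (L) and bicarbonate (B) — as a linear, lower-triangular compartment
system:

    dP/dt = u(t) − (1/T1P + kPL + kPB,direct)·P
    dL/dt = kPL·P − (1/T1L + kLB)·L
    dB/dt = kLB·L + kPB,direct·P − (1/T1B)·B

Assumptions: apparent first-order conversion (no back-reaction terms; the
rates are "apparent" precisely because reverse flux and compartmentation
are folded into them); no transverse dynamics, chemical shift, B0/B1
inhomogeneity or slice-profile effects — flips are ideal per-metabolite
scalars; magnetization is non-renewable (thermal recovery is negligible on
the hyperpolarized timescale, so T1 appears only as loss).

`kLB` is a *lumped* lactate→bicarbonate rate: conversion back through the
small intracellular pyruvate pool is treated as instantaneous because that
pool is tiny and indistinguishable from the dominant extracellular pyruvate
signal. A direct pyruvate→bicarbonate path `kPB_direct` exists as an
extension knob and defaults to 0, which recovers the lumped system exactly.

### RF handling

RF is applied as a **discrete event** at the end of each TR: the detected
sample is `Mz·sin α` and the pool retains `Mz·cos α`. Folding RF into a
continuous rate (`1/T1 − ln(cos α)/TR`, available as `effective_rate`) is
equivalent for small flips but undefined at 90°; the discrete formulation
is exact at every flip, including the saturation pulse, so it is the
default and only integration pathway. Event ordering within a step is
fixed: decay/exchange over the TR first, then excitation, with the sample
taken at the excitation; the first sample therefore falls at t = TR.

### Integration scheme

Between events the system is linear, so propagation uses the matrix
exponential — exact for the homogeneous part and for a bolus input at any
sub-step count. A time-varying supply is represented per sub-interval by
its cubic Hermite interpolant (values and analytic derivatives at the
edges), for which the driven system has an exact polynomial particular
solution obtained by back-substitution with A⁻¹ (A is lower triangular with
strictly negative diagonal). The supply's arrival-time kink at `t0` is
handled by splitting the straddling sub-interval at `t0`.

The scheme is fourth-order in the sub-step width. Measured against a
scipy adaptive integrator with RF discontinuities: max error ≈ 1.1×10⁻⁶ at
the default 16 sub-steps per TR and ≈ 4.6×10⁻⁹ at 64. Beyond roughly 256
sub-steps, cancellation in the Hermite coefficients (which scale like
1/h²) sets a roundoff floor near 10⁻⁷; there is no reason to go there —
16 sub-steps suffice for every use in the package, and the high-accuracy
cross-checks use 64.

## SNR scoring and flip-angle search

A scheme is scored by simulating the full time course, adding seeded
zero-mean Gaussian noise (default SD 10⁻³ of the bolus amplitude) to every
sample, and taking, per metabolite, the summed noisy signal divided by the
SD (ddof = 1) of that metabolite's final 10 noisy samples — by the end of a
240 s acquisition the hyperpolarized signal has decayed, so the tail
estimates the noise level. Noise is re-seeded identically across grid
cells (default seed 20220509), making sweeps deterministic and relative
curves insensitive to the noise scale. Own-flip sweeps hold the other two
metabolites at 1° by convention. Argmax ties break toward the smallest
flip (less saturation for equal SNR).

Because an unconstrained argmax of bicarbonate SNR drives the pyruvate and
lactate flips to 0° (their excitation only costs substrate), the "optimal
scheme" is operationalized as a constrained recommendation: maximize
bicarbonate SNR among grid cells where pyruvate and lactate each retain at
least a caller-chosen fraction (default 0.35) of their own maximal SNR.

## Kinetic quantification

* **Time-to-peak**: time of the global maximum sample, ties to the
  earliest; a constant curve has no peak and is rejected.
* **Gamma-variate fit**: `A·(t−t0)^α·exp(−(t−t0)/β)` by bounded least
  squares with a multi-start over the arrival time (6 candidate `t0`
  values × 2 shape starts; best RSS wins), amplitude fitted on a log
  scale. An all-zero curve returns A = 0 with a degeneracy flag rather
  than a fake fit.
* **Apparent rates (kPB, kPL)**: one-way precursor–product model
  `dX/dt = k·P_meas(t) − r_eff·X`, driven by the *measured* pyruvate
  signal, interpolated piecewise-linearly (the driven linear ODE then has
  a closed-form per-interval solution). The product's RF loss enters as
  an effective decay rate `r_eff = 1/T1 − ln(cos α)/Δt`, fixed from the
  known T1 and scheme (an override is available). The model is linear in
  the single free rate; it is fitted by bounded least squares on
  k ∈ [0, 1] s⁻¹ from a start of 0.01 s⁻¹, then snapped to the
  box-projected normal-equation solution when that does at least as well
  (this makes a zero product yield exactly k = 0). The standard error
  comes from the linearized least-squares covariance, `rss/(n−1)/ΣU²`,
  with U the unit-rate response.
* **Gates**: rates are fitted only when the product SNR strictly exceeds
  3; gated results are flagged excluded and carry no rate. A 90° product
  flip leaves no inter-sample dynamics (the pool is destroyed at every
  read), so the lactate fit refuses that arm explicitly. Curves with more
  than half negative samples are rejected as a data-quality error.

## Synthetic crossover generator

The generator emulates a paired small-animal experiment in image space:

* **Brain protocol**: 16×16 matrix, 40 mm FOV, one 16 mm slice, 40
  timepoints at 1.5 s per metabolite, flips 8°(P)/40°(B) with the lactate
  flip switched between 90° ("lactate_saturated") and 0°
  ("lactate_spared"); one elliptical organ region with
  kPL = 0.012 s⁻¹, kLB = 0.001 s⁻¹, kPB_direct = 3.7×10⁻⁴ s⁻¹.
* **Body protocol**: 20×20, 80 mm, three slices (heart/kidney/liver
  ellipses), 1.95 s resolution, same flips, and **kLB = 0** in every
  organ: the generator encodes only the observable consequence of organ
  physiology — no lactate→bicarbonate transfer — so the two arms differ
  only in the lactate pool itself and the arm effect is null by
  construction.

The direct PDH route matters: in the fully lumped model (kPB_direct = 0)
saturating lactate suppresses bicarbonate ~25-fold, which would make the
saturated arm undetectable and every saturated subject fail the SNR gate —
unlike real organ data, where both arms are measurable. `kPB_direct` is
therefore calibrated so that lactate saturation costs about 60% of the
brain bicarbonate AUC, and the noise SD (2.1×10⁻³ brain, 1.3×10⁻³ body, in
bolus-amplitude units) is calibrated to put the spared-arm bicarbonate ROI
AUC-SNR near 5.8 and the saturated arm near 3.6, so that a minority of
saturated subjects fall under the SNR-3 gate. The default supply is a
gamma-variate (shape 2, scale 1 s, arrival 1.6 s) timed so the observed
pyruvate signal peaks at 7.5 s (brain grid) / 7.8 s (body grid), a
realistic delivery delay. Per-subject variability: lognormal bolus
amplitude (σ = 15%) and uniform ±1.5 s arrival jitter, shared between a
subject's two arms; arm acquisition order alternates across subjects.

What the generator does **not** emulate — and what passing tests therefore
do not establish about real data: noise is additive Gaussian, not Rician
magnitude noise; there is no spatial point-spread, readout or
reconstruction model (images are generated directly in image space); no
perfusion heterogeneity, partial-volume or motion effects; all voxels of a
region share one kinetic parameter set. Pipeline results on this phantom
validate bookkeeping, estimator calibration and effect directions, not
in vivo effect sizes.

## Paired analysis

Each metric (per-metabolite ROI AUC-SNR, kPB, TTP) is compared as paired
spared-minus-saturated differences: mean, t-distribution 95% CI, two-sided
p-value. For a two-arm within-subject design with one observation per arm
this estimates the same arm effect as a linear mixed model with a subject
random intercept, without re-implementing REML; a tidy long-format export
(`tidy_long_table`) is provided for external mixed-model fitting.
Exclusions (SNR gate, undefined TTP, infinite SNR on noise-free data) are
counted per metric, never silently dropped; inference requires at least two
complete pairs. Zero-variance differences produce a degenerate zero-width
CI with an explicit flag. Multiple metrics are reported without
multiplicity correction, mirroring per-metric presentation; treat p-values
accordingly. AUC is a plain sum over frames and ROI curves are spatial
means — both conventions are scale choices that cancel in SNR ratios and
rate fits.

## Numerical conventions

* Flips in degrees at every interface, radians internally; times in
  seconds, rates in s⁻¹.
* Noise-window SD uses ddof = 1; the window is the final 10 samples, and
  schemes must have ≥ 20 excitations so the window sits in the decayed
  tail.
* Grid argmax ties break toward smaller flips; grid traversal order makes
  this the first occurrence in C order.
* The SNR gate is strict (`> 3`), so a value of exactly 3 is excluded.
* Seeds: every stochastic routine takes an explicit seed;
  `numpy.random.default_rng` / `SeedSequence` spawning derives per-subject
  and per-arm streams, and identical configs + seeds reproduce archives
  byte for byte.

## Known limitations

* The own-flip relative-SNR curve of any linear pool model of this kind is
  `sin α / (1 − d·cos α)` with `d = exp(−TR·r_pool)` the per-excitation
  survival factor — independent of the supply shape. The location of a
  pool's SNR optimum is therefore pinned at `arccos(d)`: ≈25° for
  bicarbonate (T1 10 s, TR 1 s) and ≈15–16° for lactate and pyruvate under
  the reference constants. Reported optima from simulation studies of this
  acquisition vary widely with the (often unstated) conventions for RF
  accounting, noise injection and SNR definition; numbers obtained under
  other conventions — including substantially higher bicarbonate optima —
  are not directly comparable to this package's sweeps, and the
  acceptance suite documents exactly this divergence.
* The precursor–product fitter ignores exchange back out of the product
  and any lactate-mediated route; when applied to three-pool data with
  kLB > 0 it absorbs the route into the apparent rate, which is precisely
  the bias the saturation comparison is designed to expose.
* T1s are fixed inputs, never estimated from data.
* No multi-compartment (glial/neuronal) model is included; the lumped kLB
  is the only trace of compartmentalized metabolism.
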