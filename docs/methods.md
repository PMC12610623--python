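# Methods

This note documents the models, numerical choices and limitations behind the
package; everything quantitative stated here is computed by the test suite or
the analysis scripts.

## FCS correlation model

The fit function is the standard 3D-Gaussian two-component diffusion model
with a multiplicative triplet factor and an additive baseline:

G(t) = (1/N)·[R·g(t; tD1) + (1−R)·g(t; tD2)]·(1 + AT·e^(−t/tT)) + b0,
g(t; tD) = (1 + t/tD)⁻¹·(1 + t/(ω²·tD))^(−1/2).

Two diffusion components are the default because labeled-protein samples
contain free dye: the fast component captures the dye, the slow one the
protein. The triplet factor multiplies the whole diffusion sum as written,
*not* the (1−AT)-normalized variant found elsewhere in the FCS literature;
with the separate baseline term this is the exact functional form the rest of
the pipeline (correlator normalization, fit defaults) is matched to.

All internal units are SI (seconds, meters, kelvin, pascal-seconds);
micro/nano conversions happen only in I/O and report formatting. The
Boltzmann constant is the CODATA exact value 1.380649×10⁻²³ J/K; solvent
conditions default to water at 25 °C (298.15 K, 0.89 cP).

Physical conversions: beam waist Wxy = √(4·D_ref·tD_ref) from a reference
dye; D = Wxy²/(4·tD); RH = kB·T/(6π·η·D). The effective focal volume
π^(3/2)·Wxy²·(ω·Wxy) is reported only together with the ω used, because ω is
rarely known independently: the calibration measurements determine Wxy but
leave the focal volume conditional on the assumed aspect ratio (script 01
tabulates V over a range of ω for exactly this reason).

## Correlator

Photon streams are binned (default 1 µs, fine enough to resolve triplet
dynamics with tT ≪ tD) and correlated with the symmetric-normalization
fluctuation estimator

G(τ=k·Δ) = (Σᵢ IᵢIᵢ₊ₖ) / ((n−k)·⟨I⟩_left·⟨I⟩_right) − 1,

where the two means run over the overlapping segments. Symmetric
normalization removes the long-lag bias of the plain estimator, so fitted
baselines come out ≈ 0 and amplitudes are directly comparable to 1/N. Lag
zero is excluded (shot-noise dominated; the model is fit on τ > 0).

The multi-tau scheme evaluates a fixed number of lags per octave (default
m = 16, the standard layout) and then coarsens the trace by summing adjacent
bin pairs, repeating until fewer than 2m coarse bins remain. On lags shared
with the direct O(n²) estimator the two agree to ~10⁻⁴ for Poisson traces of
4096 bins; the suite enforces < 10⁻³.

## Fitting

Least squares via lmfit with the trust-region-reflective backend
(`least_squares`), which handles the box constraints natively — the classic
MINPACK route stalls on this problem when bounds are active through lmfit's
parameter transformation. Initialization is physical: N from 1/G at the first
lag, the slow diffusion time from the half-decay lag, the fast one a decade
below. If a start fails, up to two additional starts with log-normally
jittered initial values (σ = 0.5, seeded) are tried and the best χ² kept, so
fits are deterministic given the seed. Parameter uncertainties come from the
covariance of the linearized problem at the optimum.

Label switching between the two diffusion components is resolved by
post-fit relabeling to tD1 ≤ tD2 (swapping R ↔ 1−R); relabeling is skipped
when the user fixed one of the times, so "fixed" always refers to the
parameter the user pinned. The recommended workflow for protein samples
fixes tD1 to the calibration dye's diffusion time and reports component 2,
and fixes ω (default 5) because ω and tD are strongly covariant.

Measured recovery, enforced by the suite: noiseless self-generated curves
recover all free parameters to better than 10⁻⁴ relative (reduced χ² < 10⁻⁸);
at 0.5% additive noise the median relative error of each free parameter over
20 seeded curves stays below 10% (the triplet lifetime is the hardest, with a
median around 7%).

## Brownian-dynamics photon simulator

Point emitters take independent Gaussian steps (per-coordinate std
√(2DΔt)) in a periodic box; per step, the expected photon count is
Δt·[background + Σ B·exp(−2(x²+y²)/Wxy² − 2z²/(ωWxy)²)·bright], counts are
Poisson-drawn and placed uniformly within the step. Periodic boundaries keep
the mean occupancy constant without injection bookkeeping. Species counts
are taken as fixed integers (not Poisson-drawn), which makes the ground-truth
occupancy N_eff = count·V_eff/V_box exact for amplitude checks.

Triplet blinking is a two-state telegraph process per particle, sampled as
alternating exponential sojourns (bright→dark at the off-rate, dark→bright
at the on-rate, equilibrium initial state) and mapped onto step midpoints.
This is exact for sojourns longer than Δt and equivalent in distribution to
per-step resolution of the telegraph process.

Validated invariants: byte-identical output per seed; photon count of a
pinned emitter Poisson around B·T; mean count rate equal to the finite-box
Gaussian-profile integral (erf product) within 3 standard errors across
seeds; first-lag correlation amplitude ≈ 1/N_eff and fitted diffusion time
within 20% of Wxy²/(4D) after the full correlate-and-fit chain.

Numerical choices: the hot path (steps, trajectories, detection profile)
runs in float32 — step noise (~10 nm) is ten orders of magnitude above
float32 resolution at box scale — with the exponential evaluated only where
the exponent exceeds −25; chunks of 20,000 steps bound peak memory. The
constructor enforces a box of at least 5 focal radii per axis and a time
step ≤ 1/10 of the fastest focal transit.

Problem sizes: validation runs use ~1–2 s of simulated acquisition at a 1 µs
step with N_eff ≈ 1 and ~35 kHz count rate (≈ 30,000 diffusion times), which
lands the recovered diffusion time and amplitude within a few percent —
comfortably inside the 20% acceptance bands — while keeping a full suite run
to about two minutes.

What the generator does *not* emulate: real detector afterpulsing and dead
time, photobleaching, optical aberrations of the point-spread function, and
the refractive-index mismatch of real samples. Passing tests therefore
demonstrate the correctness of the estimator/fit chain, not the absence of
instrumental systematics in real acquisitions.

## Z-stack axial offsets

Per ROI and channel, the z-profile is the per-slice mean over the ROI
rectangle; the peak slice is the argmax with ties broken toward the smaller
index (a perfectly flat profile returns slice 0 with a warning). Δz is
reported signed as peak(ch2) − peak(ch1), channel 2 conventionally the
deeper (protein) channel; because the sign convention of such offsets is
often ambiguous in practice, the report also carries absolute-value
summaries. Slice indices are 0-based internally with 1-based (Fiji-style)
columns in the CSV export. Pixel values are used as-is — no background
subtraction or chromatic registration, matching the descriptive character of
the measurement; sub-slice (interpolated) peak localization is out of scope.

Peak detection is integer-valued and therefore exactly robust at the noise
levels tested (Gaussian noise up to 5% of blob amplitude): the suite checks
that all 12 prescribed offsets spanning 0–41 slices in a 121-slice stack are
recovered exactly and that report summaries equal brute-force recomputation.

The synthetic stacks are sums of separable 3D Gaussian blobs plus clipped
Gaussian noise. They do not model out-of-focus haze, bleed-through between
channels, or axial anisotropy of a real PSF; they establish the correctness
of the profile/peak/offset logic, not imaging physics.

## Dosimetry

Per-cell dose = volume·concentration/cells (ng); molar-to-mass uses
concentration(µM)·volume(µL)·MW with the unit factors collapsed to
10⁻³·c·V·MW ng. Default molecular weights (overridable everywhere): Cas9
160 kDa, ~100-nt sgRNA 32 kDa, RNP their sum — per-cell RNP figures depend
on which MW convention is assumed, so the constants are explicit rather than
baked in. The BCA calibration is ordinary least squares of absorbance at
562 nm against concentration; inversion flags below-blank absorbances with a
warning instead of raising. The mass balance bound + unbound = loaded holds
exactly (unbound is computed as the difference), and efficiency is
100·bound/loaded.

All computation is full precision; rounding to the customary printed style
(2 significant figures for doses, 2 decimals for µg and percent) lives only
in the reporting layer (`round_sig`, CLI formatting, acceptance output).

## Design notes

- One umbrella CLI (`rnptrack`) with `fcs`/`zoffset`/`dose` groups: one
  install, one docs entry point; every output gets a JSON sidecar recording
  inputs, parameters, seed and package version, and reruns with the same
  seed are byte-identical.
- The photon binary format (`FCSPHOT1`, ns-resolution uint64 timestamps)
  intentionally carries no duration field; readers default the duration to
  the last timestamp unless told otherwise, while the CSV form records the
  duration in a comment.
- Curve CSVs store 17 significant digits so a written curve refits to the
  bit-identical result.

## Known limitations

- The correlator is a software multi-tau on binned traces, not a hardware
  correlator emulation; extremely fast dynamics below the initial bin width
  are invisible.
- The fitter reports linearized standard errors; strongly correlated
  parameter pairs (ω with tD, AT with N) need one of them fixed for the
  errors to be meaningful.
- The axial-offset measurement has slice-level resolution by design; offsets
  smaller than the slice spacing quantize to 0 or ±1.
- Aggregation states between monomer and large aggregate produce intermediate
  apparent radii; the two-component model resolves two species, not a
  continuous size distribution.
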