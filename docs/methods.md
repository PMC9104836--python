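# Methods

## The imaging model

Fourier ptychographic microscopy (FPM) acquires a stack of low-resolution
(LR) intensity images under angularly varied LED illumination and
synthesizes a high-resolution (HR) complex object by stitching the
corresponding sub-apertures in Fourier space. With `u` the complex object
on the HR grid, `s = F u` its centered spectrum, `Q_j` the m×m window of
the HR spectrum selected by the j-th LED's plane-wave tilt, and `p` the
complex pupil transfer function of the objective, each captured frame is

    I_j = | F^H { p ⊙ Q_j s } |²,    A_j = √I_j.

All transforms are unitary with centered (fftshift) spectra, so Parseval's
identity holds exactly and `Q_jᵀ` (zero-padded embedding) is the exact
adjoint of the window crop. LED tilt frequencies are rounded to the nearest
HR Fourier bin; the rounding lives in one place (`sampling_window`).
Windows that would leave the HR grid are a configuration error, never
wrapped.

The pupil is a circular aperture of radius `NA_obj/(λ·Δf)` pixels
(`Δf = 1/(m·pixel)`, with the object-plane pixel = sensor pixel /
magnification), unit modulus inside, zero outside; its phase is a
Noll-indexed Zernike expansion in radians. The default platform is a
4×/0.1 NA objective with 6.5 µm sensor pixels, a 15×15 LED array at 86 mm
height and 4 mm pitch, 632 nm illumination, 128² LR patches reconstructed
on a 384² HR grid (aperture radius ≈ 33 px; per-pitch spectral shift ≈ 15
bins, i.e. ≈ 77 % linear overlap between adjacent sub-apertures).

## Blind reconstruction by ADMM

The solver splits the bilinear measurement constraint from the modulus
fidelity by auxiliary spectra `q_j` with scaled multipliers `ω_j`, plus a
Tikhonov anchor `(γ/2)‖s − δ‖²` toward the spectrum `δ` of a flat light
field (weak-phase stabilizer). One iteration (batch schedule):

1. `q_j ← q̃ + (F[A_j ⊙ e/|e|] − q̃)/(1+α)` with `q̃ = p ⊙ Q_j s − ω_j`,
   `e = F^H q̃` — a relaxed projection onto the measured-modulus set
   (α = 0 projects exactly; α → ∞ freezes).
2. `s ← [γδ/α + Σ_j Q_jᵀ(conj(p)(q_j+ω_j))] / [γ/α + Σ_j Q_jᵀ|p|²]`
   elementwise (the normal operator is diagonal). With γ = 0, HR bins
   covered by no window keep their previous value.
3. `p ← [Σ_j conj(Q_j s)(q_j+ω_j)] / [Σ_j |Q_j s|² + β]`, re-masked by the
   aperture support.
4. `ω_j ← ω_j + η (q_j − p ⊙ Q_j s)`.

Convergence is monitored by normalized error metrics: `E_p` (data misfit
over `Σ‖A_j‖²`) and `E_d` (iterate change over `Σ‖λ_j‖²`, `λ_j = α ω_j`);
the loop stops when the relative change of both falls below `eps_tol`
(default 1e-3), with `E_d` participating only once two finite values
exist. A guard aborts if `E_p` exceeds 10⁶ × its initial value. There is no
theoretical convergence guarantee for this non-convex problem; the
iteration is empirically stable at the default parameters.

Parameter defaults follow the suggested ranges: α = 0.5, β = 1000, γ = 0.3,
η = 1, 100 iterations, updates in NA-ascending ("center-out") order with
(row, col) tie-breaks, and a flat-field start (which outperforms the
center-LED upsampling start for this solver). Two conventions deserve
comment:

* **β scale.** β ≈ 1000 is calibrated against spectra produced by
  unnormalized DFTs, the customary convention in FPM code. Our unitary
  spectra are m times smaller, so `|Q_j s|²` is m² smaller and the solver
  internally uses `β/m²`; with β = 1000 applied raw, the pupil update is
  crushed to near zero and reconstruction fails.
* **δ scale.** The flat-field anchor is matched to the data: a uniform
  object of amplitude `a₀` yields a brightfield mean intensity
  `(a₀·n/m)²`, so `δ = F[a₀·1]` with `a₀ = (m/n)·√(max brightfield mean)`.
  Anchoring at unit brightness regardless of the data biases the object
  toward the wrong scale and visibly degrades phase recovery.

The per-illumination nested variant of the update schedule (s, p, ω
refreshed inside the j-loop) is available via `schedule="sequential"`; the
batch schedule is the default and is what the update equations themselves
describe.

Measured stacks are intensities; all fidelity terms consume amplitudes
`A_j = √I_j` — the modulus projection is only dimensionally consistent for
amplitudes. The stopping criteria compare |relative change|; the signed
form would fire immediately on any decreasing error sequence.

## Baseline solvers

Both baselines sweep illuminations sequentially in NA order, replace the
modulus of the exit field by the measurement, and write quotient
corrections back into the object-spectrum window and the pupil. They start
from the center-LED image upsampled by Fourier embedding (brightness-
preserving under unitary transforms) and share the data container, NA
ordering and `E_p` metric with the ADMM solver.

**Adaptive-step Gauss–Newton.** Pupil-weighted second-order quotient
updates with `|p|`/`|Q_j s|` max normalization and small relative Tikhonov
floors (1e-3); after every sweep both step sizes pass the self-adaptive
rule: halve when the relative error increase exceeds ε = 0.01, keep
otherwise (initial steps α⁰ = β⁰ = 1). Steps are therefore non-increasing.

**Momentum PIE.** rPIE-style quotient updates (object denominator weight
α = 0.1, pupil weight β = 0.8), pupil updates released at the 15th
illumination position, and a per-sweep velocity step
`v ← η v + (1−η) Δ_sweep`, `x ← x + γ v` with η_obj = 0.9, η_pupil = 0.3,
friction γ = 1. The velocity step is accepted only if it does not increase
`E_p` and the velocities are reset otherwise (an adaptive-restart
safeguard). This matters: unguarded extrapolation of the *pupil* — at any
weight we tested down to 0.05 — excites the slow object/pupil joint
ambiguity (object phase ramp ↔ pupil tilt, plus global phase/scale trades)
and drives the error up by two orders of magnitude within ~10 sweeps.
With the safeguard, momentum is a strict no-loss accelerator.

## Noise models

Both models perturb only frames whose mean intensity falls below 0.2 after
the stack is normalized so the brightest brightfield frame has mean 1
(darkfield frames carry the weak, noise-prone high-angle signal):

* Gaussian: zero-mean with σ = level × mean(frame), clipped at zero
  (detectors are nonnegative). "70 % noise" means level = 0.7.
* Poisson: `I ← σ·Poisson(I/σ)` — mean-preserving with variance σ·I, so σ
  acts as the intensity quantum per photon count and σ → 0 recovers the
  noiseless frame. Note the direction: in this construction larger σ means
  *more* noise; the often-quoted opposite phrasing is inconsistent with
  any mean-preserving Poisson surrogate, and we keep the construction
  (which is the stated one) over the phrasing.

All noise is injected through `numpy.random.default_rng(seed)` and is
bit-reproducible.

## Synthetic ground truth

The test images are procedural: random-phase fields with
power-law amplitude spectra (|S| ∝ f^−1.2, natural-scene statistics) plus
a few periodically wrapped Gaussian blobs, generated in the Fourier domain
and hence exactly periodic — matching the FFT forward model and avoiding
edge ringing. Amplitude spans [0.4, 1] (kept away from zero so amplitude
and phase stay separable); phase spans [0, π/2] (weak-phase regime of thin
sections). Roughly a third of the image energy lies beyond the objective
passband, so darkfield frames carry genuine signal and noise robustness is
actually exercised; a smoother generator (our first draft) concentrated
>99.999 % of the energy inside the passband and made the noise study
vacuous. What these images do **not** emulate: real LED position errors,
intensity miscalibration, vignetting, partial coherence, or sensor
quantization — passing tests say nothing about those effects.

The default simulated aberration is defocus 0.5 rad, oblique astigmatism
−0.3 rad, vertical coma 0.2 rad (Noll 4, 6, 8).

## Evaluation

Reconstructions are scored by SSIM after removing the phase-retrieval
ambiguities: integer translation (modulus cross-correlation), global phase
(angle of ⟨recon, truth⟩), and global amplitude scale (least squares).
Phase maps are shifted by a common constant into the nonnegative range
SSIM requires. The windowed SSIM (standard 7-pixel windows, k₁ = 0.01,
k₂ = 0.03 on the joint dynamic range) is the default; the single-statistic
global form is available via `SSIMConfig(windowed=False)`. Pupil recovery
is scored by the Pearson correlation of the phase maps inside the aperture
mask.

Convergence speed is compared across solvers by a *common accuracy rule*:
the iteration count to reach the same normalized error level, 1e-4. The
solvers' own stopping rules differ in kind (ADMM: both residual criteria;
Gauss–Newton: step-size decay; mPIE: error stability), so relative-change
rules are not comparable across them; moreover the sequential solvers fit
noiseless data to machine precision with exponentially decaying error, so
a pure relative-change rule never fires for them. At the 1e-4 level the
ranking (momentum PIE fastest, Gauss–Newton second, ADMM slowest — ADMM's
error floor under its Tikhonov bias sits near 2e-4 and does not reach the
level within its 100-iteration budget) is stable across every truth seed
we checked.

## Problem sizes

The package's own studies run at two sizes chosen to keep a full study on
one CPU comfortable: the full platform (225 LEDs, 128² → 384², ~50 s per
100-iteration solve) for the noiseless comparisons, and a reduced profile
(9×9 LEDs at the same geometry, 64² → 192², ~7 s per solve) for the
5-seed noise sweeps. Solver-level unit tests use a 7×7-LED, 32² → 96²
profile whose synthetic aperture covers only part of the HR band; SSIM
bars there are smoke-level (≥ 0.8 ideal-pupil) by construction, with the
quantitative ≥ 0.85 bars reserved for the full platform.

## Known limitations

* Single-patch reconstruction only: no full-FOV segmentation/stitching, no
  LED misalignment calibration, no vignetting model.
* The Tikhonov anchor biases the ADMM solution toward the flat field;
  its data-misfit floor is nonzero and γ trades noise robustness against
  that bias.
* Sub-pixel LED frequencies are rounded to integer bins; at the simulated
  geometries the rounding error is ≤ 0.5 bins and is shared by simulator
  and solvers, so it is invisible to the tests; on real data it would
  appear as a small model mismatch.
* The standard-form ADMM variant and self-adaptive ADMM step sizes are
  deliberately out of scope.
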