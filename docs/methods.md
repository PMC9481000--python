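# Methods

## Model

Continuous-wave DCS observes the normalized field autocorrelation g₁(ρ, τ) of
diffusely reflected coherent light at source–detector (SD) distance ρ. In the
diffusion regime G₁ obeys the correlation diffusion equation
`[∇² − αₙ²(τ)] G₁ = −s₀ δ(r − r′)` with, per layer n,

    αₙ²(τ) = 3 μa,n μs′,n + 6 τ kₙ² D_B,n μs′,n²
           = 3/(lₙ* lₙᵃ) + 6 τ / (τₙ(0) lₙ*²),

where lₙ* = 1/μs′,n and lₙᵃ = 1/μa,n are the transport and absorption mean
free paths, kₙ = 2πnₙ/λ the in-medium wavenumber and τₙ(0) = (kₙ²D_B,n)⁻¹ the
single-scattering decorrelation time. The scatterer dynamics are effective
Brownian motion, ⟨Δr²(τ)⟩ = 6 D_B τ; D_B (times the moving-scatterer fraction
α where applicable) is the flow index.

Two forward solutions are implemented.

**Homogeneous semi-infinite (conventional).** The image-source closed form
with K(τ)² = 3μaμs′ + 6μs′²k₀²·(αD_B)·τ, source depth z₀ = 1/μs′ and
extrapolation length z_b = (2/(3μs′))(1+R_eff)/(1−R_eff), with
R_eff = −1.44n⁻² + 0.71n⁻¹ + 0.064n + 0.668. This is the model whose single
fitted parameter is αD_B.

**Two-layer Fourier-domain.** A slab (thickness d₁, static in the intended
use: D_B1 = 0) over a semi-infinite dynamic layer. In the transverse Fourier
domain the surface Green's function is a ratio of cosh/sinh combinations of
β₁d₁ (see the README for the closed form) with βₙ = sqrt(αₙ² + q²) and photon
diffusion coefficients Dₙ = c lₙ*/3, c the in-medium light speed. Real-space
curves follow from the inverse Hankel transform
G₀(ρ,τ) = (1/2π)∫Ĝ₀(q,τ) q J₀(ρq) dq and normalization g₁ = G₀(τ)/G₀(0),
which cancels the source constant. The implementation was verified against an
independently assembled piecewise-exponential solution of the depth ODE
(continuity of G and D∂G at the interface, Robin condition G = z₀∂G at the
surface): the two agree to machine precision up to a constant factor.

### Boundary length z₀

Two conventions exist for the boundary length that appears in the
denominators: the transport mean free path 1/μs′(1) ("mfp") and the
partial-flux extrapolation length z_b of the top layer ("extrapolated"). Both
are implemented behind `boundary_length_mode`; the default is "extrapolated",
the physically standard choice for index-mismatched boundaries. All shipped
analyses record the mode used. The source depth z′ = 1/μs′(1) is fixed.

### Parameters and defaults

| parameter | default | unit | rationale |
|---|---|---|---|
| top μa, μs′ | 0.11, 8.50 | cm⁻¹ | solid skull-surrogate baseline |
| bottom μa, μs′ | 0.12, 10.46 | cm⁻¹ | liquid cortex-surrogate baseline |
| n (top / bottom) | 1.40 / 1.33 | – | typical silicone / water-based values |
| λ | 785 | nm | standard DCS wavelength |
| D_B2 | 2×10⁻⁹ | cm²/s | mid-range of the diagnostic contour axis; a configurable stand-in, since all comparisons are relative |
| β | 0.5 | – | single-mode-fiber detection |
| fit window | [10⁻⁶, 3×10⁻³] | s | standard two-layer fit range |
| β window | [0.5, 0.8]×10⁻⁶ | s | earliest-lag estimate of the Siegert factor |
| bounds | d₁∈[0,20] mm, D_B2∈[0,10⁻⁶] cm²/s | | physical search ranges |

Internal units are cm/s/cm²·s⁻¹; the CLI speaks mm for thicknesses and SD
distances.

## Numerics

**Hankel quadrature.** The q integral is split into panels at successive
zeros of J₀(ρq), each integrated by fixed-order Gauss–Legendre (order 20 in
the forward path), with the upper cutoff chosen where the τ = 0 integrand
falls below 10⁻¹² of its peak (floor 20·μs′(1), cap 60·μs′(1)). The
self-refining scalar transform doubles the order until successive estimates
agree to 10⁻⁸ relative, with an absolute floor at the roundoff of the
oscillatory sum, and raises with diagnostics if convergence fails. The fixed
rule agrees with the self-refining one and with fine-grid Simpson references
to better than 10⁻⁶ relative on all shipped integrands.

**Overflow-safe slab ratios.** cosh(β₁(d₁−z′))/cosh(β₁d₁) and its sinh
companion are evaluated via explicit exponentials of non-positive arguments;
the naive tanh form loses all precision once β₁z′ ≳ 18.

**Estimation.** All fits are deterministic. The one-parameter models use a
coarse logarithmic grid (61 points over 10⁻¹²–10⁻⁶ cm²/s, plus the exact
zero-flow candidate) followed by bounded scalar minimization in log-space;
a boundary solution at zero flow is flagged as non-converged. The two-layer
model scans d₁ in 0.5 mm steps over [0, 20] mm × 30 log-spaced D_B2 values
(on a decimated lag grid with a low-order quadrature — the coarse stage only
places the start), then refines with bounded Nelder–Mead in (d₁, log₁₀D_B2)
(xatol 10⁻⁶, fatol 10⁻¹², ≤500 iterations). Standard errors come from a
finite-difference Gauss–Newton linearization. A dense unweighted RSS surface
over (d₁, D_B2) serves as a global-minimum fallback: its argmin replaces the
optimizer's solution only when it undercuts the optimizer's RSS by more than
10⁻³ relative (strict inequality).

**Weighting.** With per-lag SNR available, squared residuals are weighted by
the SNR normalized to unit sum; non-finite or non-positive SNR lags are
excluded from the weighted objective. Constant SNR reduces exactly to the
unweighted fit.

**Degenerate inputs.** Flat curves fit to the zero-flow bound with a
non-convergence flag; identical-snapshot ensembles yield an infinite-SNR
sentinel excluded from weights; semi-infinite thickness is an explicit
sentinel (`None`), never a large number; d₁ ≤ z′ triggers a warning (the
source would sit below the interface) but evaluates.

## Synthetic data

The generator emulates a two-layer phantom ladder: a static solid slab
(2.01–8.08 mm in seven steps) over a shared dynamic liquid half-space, plus
the slab-free homogeneous reference, measured at SD = 10/15/20/25 mm with
2 Hz snapshots over 100 s. Noise is an independent Gaussian perturbation per
lag and snapshot with σ = sqrt(mean g₂ / (count_rate · bin_time)) — a
shot-noise-style approximation adequate for exercising SNR estimation,
weighting and averaging, but not a hardware-validated correlator noise model:
it has no lag-to-lag correlations, afterpulsing or dead-time effects, and the
count-rate decay with slab thickness (exp(−d₁/5 mm)) is phenomenological.
The per-detector count rate defaults to 50 kHz, a typical DCS operating
point. Passing tests on these synthetics demonstrates correctness of the
analysis pipeline, not fidelity to any particular instrument.

The lag grid is quasi-logarithmic (128 points, 1.5×10⁻⁷–10⁻¹ s), covering
the β window and fit window with margin. Simulations are bit-reproducible
given a seed (per-SD child streams from a seed sequence).

## Analyses

* **Flow comparison.** Per preset/SD, the conventional αD_B and two-layer
  D_B2 are expressed as percent differences from the homogeneous-reference
  fits (conventional and Fourier-domain homogeneous, respectively) — the
  protocol that makes the two one-parameter quantities commensurable.
* **Optical-property perturbations.** Curves generated at truth are refitted
  with exactly one coefficient (μa or μs′ of either layer) scaled by 0.8 or
  1.2; percent changes of d₁ and D_B2 are reported per thickness plus the
  mean over the 2.01–4.99 mm slabs. Perturbations are never applied jointly.
* **Thickness trend.** OLS of fitted vs. true d₁ with the exact-t two-sided
  slope p-value, optionally restricted to d₁ ≤ 4.99 mm where the relation is
  linear. No multiple-testing correction is applied (single pre-specified
  regression per SD).

The default sweeps use noise-free forward curves, isolating model-induced
bias from noise; the acquisition pipeline provides the noisy mode.

## Known limitations and expected deviations

* The model-only surrogates do not reproduce every statistic measured on
  physical phantoms. In particular, the noise-free single-layer flow bias
  under a 2.01 mm static top is −43/−33/−26/−22% at SD = 10/15/20/25 mm
  (mean magnitude ≈ 31%), growing monotonically with thickness and reaching
  ~65% only near d₁ ≈ 4.3 mm, whereas phantom measurements have shown ~65%
  already at the thinnest slab. Contact/coupling effects, the true liquid
  flow index and optical-property uncertainty of a physical phantom are
  outside this model.
* The earliest-lag β estimate inherits a small negative bias from the
  residual g₁ decay inside its window (≈0.5–1% at these parameters). Under
  SNR weighting, which concentrates on early lags, that bias propagates into
  a D_B2 underestimation of up to ~10% for the thinnest slab at
  SD = 25 mm through the full pipeline; comparisons made relative to a
  homogeneous reference processed through the same pipeline largely cancel
  it, and thicker slabs are less affected.
* Two layers only, with a strictly static top (D_B1 fixed, default 0); no
  scalp flow, no three-layer geometry, no curved surfaces, no Monte Carlo
  transport, and no time- or frequency-domain variants. Multi-distance joint
  fitting is not implemented.
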