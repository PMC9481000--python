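# dcslayer

Two-layer analytical modelling for continuous-wave diffuse correlation
spectroscopy (DCS).

DCS measures deep-tissue microvascular flow from the temporal fluctuations of
multiply scattered coherent near-infrared light: the normalized intensity
autocorrelation g₂(τ) is converted through the Siegert relation
g₂ = 1 + β|g₁|² to the field autocorrelation g₁(τ), whose decay rate encodes
the Brownian diffusion coefficient D_B of the moving scatterers (the flow
index). The conventional analysis assumes a homogeneous semi-infinite medium —
a poor description of the head, where light must cross the static scalp and
skull before sampling the cortex.

This package implements, tests and exercises a two-layer alternative: a
static slab of finite thickness d₁ (skull surrogate) over a dynamic
semi-infinite medium (cortex surrogate). Fitting the two-layer solution to a
single measured g₁ curve recovers the slab thickness d₁ *and* the
bottom-layer flow index D_B2 simultaneously. It is written for researchers in
biomedical optics who want a transparent, instrument-free reference
implementation of that analysis — including the synthetic phantom study
needed to characterize it.

## The model

The field autocorrelation G₁(r, τ) obeys the correlation diffusion equation
`[∇² − αₙ²(τ)] G = −s₀ δ(r − r′)` with the per-layer decay coefficient

    αₙ(τ) = sqrt( 3 μa,n μs′,n + 6 τ kₙ² D_B,n μs′,n² ),

where μa and μs′ are the absorption and reduced scattering coefficients,
kₙ = 2πn/λ the in-medium wavenumber, and D_B,n the layer's Brownian
coefficient. Solving in the transverse Fourier domain for a slab of thickness
d₁ on a half-space gives the surface Green's function

    Ĝ₀(q, τ) = z₀ [β₁D₁ cosh(β₁(d₁−z′)) + β₂D₂ sinh(β₁(d₁−z′))] /
               [β₁(D₁+β₂D₂z₀) cosh(β₁d₁) + (β₂D₂+β₁²D₁z₀) sinh(β₁d₁)],

with βₙ(q,τ) = sqrt(αₙ² + q²), Dₙ = c lₙ*/3 the photon diffusion
coefficient, z′ = 1/μs′(1) the source depth and z₀ the surface boundary
length. The measured autocorrelation follows from the inverse Hankel
transform G₀(ρ, τ) = (1/2π) ∫ Ĝ₀(q, τ) q J₀(ρq) dq, evaluated here with a
panel quadrature split at the zeros of J₀, and normalized to
g₁ = G₀(ρ,τ)/G₀(ρ,0). The conventional single-layer model (image-source
closed form with the extrapolated boundary) is included for comparison.

Inversion fits (d₁, D_B2) within bounds d₁ ∈ [0, 20] mm and
D_B2 ∈ [0, 10⁻⁶] cm²/s, minimizing the SNR-weighted squared residual of g₁
on τ ∈ [10⁻⁶, 3×10⁻³] s with a deterministic coarse grid followed by bounded
Nelder–Mead refinement; a dense RSS (residual sum of squares) surface over
(d₁, D_B2) provides a global-minimum fallback and contour diagnostics.

## Worked example

```python
import numpy as np
import dcslayer as dl

# a 3.87 mm static slab over a dynamic half-space (phantom preset P3)
p3 = [p for p in dl.phantom_presets() if p.label == "P3"][0]

# simulate a 100 s, 2 Hz acquisition at SD = 25 mm and average it
spec = dl.AcquisitionSpec(sd_mm=(25.0,), seed=7)
avg = dl.average_curve(dl.simulate_acquisition(p3.medium(), spec)[25.0])

# standard pipeline: coherence factor, Siegert inversion, two-layer fit
beta = dl.estimate_beta(avg)          # 0.4970
g1 = dl.g2_to_g1(avg, beta)
fit = dl.fit_two_layer(g1, p3.medium(), rho=2.5)
print(fit.summary())
```

prints

```
DCS fit: two_layer
  n_points: 76
  converged: True
  RSS (unweighted): 2.692680e-03
  RSS (weighted):   5.239228e-06
  parameters:
    d1 = 0.371928 +/- 0.005212 cm
      (3.719 mm)
    d_b2 = 1.89893e-09 +/- 2.581e-11 cm^2/s
  tau_range_s: (1e-06, 0.003)
  rho_cm: 2.5
  boundary_length_mode: extrapolated
  d1_bounds_cm: (0.0, 2.0)
  db2_bounds: (0.0, 1e-06)
  weighted: True
```

The true thickness is 3.87 mm and the injected flow index 2×10⁻⁹ cm²/s: the
noisy single-distance fit recovers the thickness within ~4% and the flow
within ~5%. A conventional single-layer fit of the same curve
(`dl.fit_single_layer_conventional`) returns αD_B ≈ 1.05×10⁻⁹ cm²/s — a
47% underestimation caused by the static top layer, which is the bias the
two-layer model exists to remove.

The same operations are available from a shell:

```
dcslayer presets
dcslayer simulate --preset P3 --sd-mm 25 --seed 7 --out sim/
dcslayer fit --curve sim/g2_sd25mm.tsv --preset P3 --model two-layer --out fit.json
dcslayer contour --curve sim/g2_sd25mm.tsv --preset P3 --out surf
dcslayer sensitivity --analysis perturbation --preset P3 --sd-mm 20 --out sens.tsv
```

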