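# Methods

## Overview

`porodiff` quantifies the sub-micrometre structure of water-saturated porous
polymer matrices from two complementary measurements, both implemented here
end-to-end on synthetic data with known ground truth:

1. **Anomalous-subdiffusion MRI.** A pulsed-gradient stimulated-echo (PGSTE)
   imaging experiment measures the signal ratio
   `S(q, Δ)/S(0, Δ) = exp(-K_α q² Δ^α)` as a function of diffusion time Δ.
   The voxelwise anomalous exponent α, averaged over the x, y and z gradient
   directions (Mα), maps onto the walk dimension of the water random walk,
   `d_w = 2/Mα`, and decays with the specific pore surface area S as
   `Mα(S) = (1 - Mα∞) exp(-S/σ) + Mα∞`. Reading this relation off at the 2D
   percolation-threshold exponent (`d_w = 2.87`, `α_c ≈ 0.70`) yields the
   critical surface area `S_c = σ ln[(1 - Mα∞)/(α_c - Mα∞)]`, which is
   `σ ln 10` for the plateau `Mα∞ = 2/3`.
2. **Local porosity theory (LPT) dielectric spectroscopy.** The effective
   complex permittivity ε\*(ω) of the water/polymer composite solves a
   self-consistent mixing integral over the local porosity distribution
   μ(ϕ) (truncated Gaussian, mean ϕ0, variance Var) and the local
   percolation probability λ(ϕ) = ϕ^Γ. The inverse problem fits (Γ, ϕ0,
   Var) to a broadband spectrum (1 kHz–2 GHz).

## Signal models and conventions

* Wavevector `q = γ g δ / 2π`; all quantities SI internally.
* b-value: the standard Stejskal–Tanner `b = (γ g δ)² (Δ - δ/3)`. A
  literature variant `b = γ g δ² Δ` circulates but is dimensionally
  inconsistent with `exp(-bD)`; only the standard form is implemented.
* In the `q = γgδ/2π` convention the stretched model at α = 1 reduces to
  `exp(-K q² Δ)` while the Brownian decay is `exp(-(2πq)² D Δ)`; matching
  the two fixes `K = (2π)² D`. The phantom generator therefore defaults to
  `K_mean = (2π)² · 2.0e-9 ≈ 7.9e-8 m² s^-α`, i.e. free water
  (D ≈ 2.0e-9 m²/s near 18 °C) at α = 1. With the protocol below this puts
  the measured ratios in the 0.38–0.94 range — a well-conditioned decay.
* Asymptotic validity of the stretched form is flagged when
  `K_α q² Δ^α > 1` (more than one e-fold of decay); the low-q derivation
  assumes small attenuation and 1.0 keeps fitted decays within one e-fold.

## Acquisition protocols (defaults)

* α branch: 8 log-spaced Δ in [20, 250] ms, δ = 2 ms, g ∈ {0, 74} mT/m,
  directions x, y, z; 128×128 matrix, FOV 0.8 cm (voxel 62.5 μm), slice
  1 mm.
* MD branch: Δ = 100 ms, b0 plus six non-coplanar directions
  (±45° pairs in the coordinate planes), same geometry.

## Synthetic phantoms

Each sample is a circular region (7 mm diameter in the 8 mm FOV) of voxels
with independent truncated-normal (α, K_α, D) fields; no spatial texture is
simulated, since only ROI distributions are analysed. A stimulated-echo
longitudinal decay `exp(-Δ/T1)` (T1 = 1.5 s) multiplies every acquisition
and cancels exactly in the g>0/g=0 ratio — it is kept to prove that
cancellation. Noise is Rician (modulus of a complex Gaussian) applied to
magnitudes *before* the ratio is formed, at a single-scan SNR of 50
(an assumption; the real acquisitions' SNR is not documented) with the
32-scan averaging emulated by dividing the noise standard deviation by
√32 — statistically equivalent to and 32× cheaper than simulating repeats.

The three-sample scenario sets the per-sample α mean from the Mα(S)
relation with σ = 301.8 m²/g (so that S_c = σ ln 10 ≈ 695 m²/g) and
Mα∞ = 2/3 at the measured surface areas S = 16 (G80), 100 (G60) and
188 m²/g (G40), giving means 0.983, 0.906 and 0.845. The voxel α spread is
0.04, comparable to the fit noise at SNR 50, so the ROI distributions
overlap realistically. The diffusivity field (mean 2.0e-9 m²/s, sd
1.0e-10) is identical across samples by construction: MD cannot carry
sample information, which is exactly the contrast the analysis must expose.

What passing tests show — and what they do not: recovery and
discrimination results validate the estimators under the stated noise
model on spatially uncorrelated fields; they do not speak to scanner
artifacts (eddy currents, drift), partial-volume or susceptibility
effects, spatially structured heterogeneity, or exchange between water
pools, none of which are simulated.

## Voxelwise fitting

The α fitter minimises least squares of `exp(-K q² Δ^α)` against the
ratio series with a Levenberg–Marquardt iteration vectorised across all
voxels at once (2×2 normal equations per voxel). Bounds α ∈ [0.1, 1.5],
K > 0 are enforced by the smooth reparametrisation
`α = 0.1 + 1.4·logistic(u)`, `K = exp(v)`. Two starts are run — the
log-log linearisation `ln(-ln R) = ln(K q²) + α ln Δ` over points with
R < 0.99, and a Brownian α = 1 start — and the lower-cost solution kept.
Convergence: cost change < 1e-10, at most 200 iterations. Voxels with no
measurable decay (all ratios ≥ 0.99) or with a g = 0 signal below 5× the
background noise estimate (mean magnitude over the four 8×8 corner
patches) are masked; the Rician bias of the ratio explodes at low SNR.

MD is one third of the trace of a diffusion tensor fitted log-linearly to
the b0 + six-direction signals ("trace/3" is the community convention for
mean diffusivity; a bare trace would be 3× larger and mislabel the maps).
ADC fits weight the log-linear regression by the squared signal, the
standard correction for log-transformed exponential noise.

ROI statistics use voxel-centre membership in a circle of 80% of the
sample radius (the exact analysis ROI is a free choice; 80% avoids edge
voxels). Discrimination between samples is Cliff's delta
`P(x > y) - P(x < y)`, computed exactly by rank counting.

## Percolation calibration

The (0, 1) free-water anchor is included in Mα(S) fits by default — it is
a physically exact point, not an extrapolation. With the plateau fixed at
2/3 the critical surface area is `σ ln 10` exactly. Two threshold numbers
circulate (d_w = 2.87 from lattice simulations, α_c = 0.70 = 2/2.857
rounded); the constants store both and enforce `α_c · d_w ≈ 2` within
0.01. The Padé approximant `d_w(x) = (2 + 2x + x²/6)/(1 + x/2 + x²/12)`,
x = S/σ, agrees with `2/Mα(S)` within 0.12 over x ∈ [0, 4] and both equal
2 at x = 0; the two forms diverge outside the measured range (the Padé
tends to 2 as x → ∞, the exponential form to `2/Mα∞` = 3), so the
agreement property is only asserted on [0, 4].

## Dielectric solver

Numerical choices:

* μ(ϕ) is a Gaussian truncated to [0, 1]; its weights are renormalised on
  the quadrature rule itself, so ∫μ = 1 holds exactly in quadrature and
  the bulk porosity Φ = ∫ϕμ dϕ is consistent. Var ≤ 1e-12 degenerates to
  a point mass at ϕ0.
* Fixed Gauss–Legendre quadrature with 128 nodes on [0, 1] (cached).
  Doubling the nodes changes solved permittivities by < 1e-8 relative on
  the default parameter ranges; 64 nodes miss that criterion (~4e-8).
* Internal sign convention ε\* = ε′ − iε″ with ε″ ≥ 0 throughout; the
  conductivity term of water enters as `-i σw/(ε0 ω)`. A single internal
  convention avoids branch errors in the complex Newton iteration.
* The effective cell permittivities εwe\*(ϕ), εpe\*(ϕ) satisfy the four
  physically forced limits (a cell of porosity 1 is pure water, of
  porosity 0 pure polymer); these limits pin the algebraic form and are
  enforced as tests.
* Root finding: damped complex Newton with the analytic derivative
  `d/dε (a-ε)/(a+2ε) = -3a/(a+2ε)²`, backtracking to keep Re ε > 0,
  tolerance |residual| < 1e-10. Starts, in order: the continuation seed
  (previous frequency's root), the λ-mixture guess at ϕ0, the two
  component-dominated limits, 10 seeded random perturbations, and — as a
  last resort — a coarse complex-plane grid scan to locate the basin
  (needed for barely-percolating media, whose nearly lossless root sits
  far from the conduction-dominated mixture guess). The lossy branch
  (Im ε ≤ 0) nearest the seed is kept.
* Inversion: multistart (5 seeded starts) bounded least squares over
  Γ ∈ [0, 20], ϕ0 ∈ (0.01, 0.99), Var ∈ [0, 0.25], objective = relative
  misfit of ε′ and ε″ stacked over frequencies. Component properties
  (εw = 78.5, σw = 0.1 S/m, εp = 3) are fixed inputs. Starts whose forward
  solve fails anywhere are abandoned; an error is raised only if all fail.

## Problem sizes

All image experiments run at the full acquisition size (128×128, 8 Δ, 3
directions); the vectorised fitter makes a full slice fit take well under
a second, and the 20-seed three-sample sweep about 10 s. Dielectric fits
use 50 log-spaced frequencies over 1 kHz–2 GHz.

## Known limitations

* The stretched-exponential model is fitted per voxel independently; no
  spatial regularisation.
* Rician noise is tolerated, not modelled: the fitter is least squares on
  the ratio, with the noise-floor mask as the only guard. A
  Rician-likelihood fitter would reduce residual bias at SNR ≲ 10.
* The Mα(S) calibration with a free plateau is weakly identified when no
  samples approach the plateau (the three measured S values all sit on
  the decaying flank); the fixed-plateau variant (Mα∞ = 2/3) is
  recommended and used for S_c extraction.
* λ(ϕ) = ϕ^Γ and Gaussian μ(ϕ) are parametric conveniences; other
  families are out of scope.
* 2D percolation exponents are used throughout (thin-slice geometry); no
  3D variant is provided.
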