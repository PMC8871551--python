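# porodiff

Anomalous-subdiffusion MRI and dielectric analysis of water-saturated
porous polymer matrices.

## The problem

Macroporous polymers (polyHIPE monoliths and similar matrices) hide their
functionally important structure below the resolution of conventional MRI:
micrometre voids interconnected by sub-micrometre windows, with pore-wall
roughness down to tens of nanometres. Water diffusing through such a
medium is *transiently subdiffusive* — its mean-squared displacement grows
as

    MSD ∝ t^(2/d_w),      d_w ≥ 2,

where the walk dimension d_w exceeds the Brownian value 2 by an amount set
by how strongly the fractal pore-wall microstructure obstructs the walk.
`porodiff` implements the complete analysis chain that turns
diffusion-weighted image series and broadband permittivity spectra into
quantitative microstructure parameters, together with seeded synthetic
generators so every stage is testable without scanner data.

## The models

**Subdiffusion imaging.** A PGSTE sequence with gradient strength g, pulse
duration δ and diffusion time Δ measures, per voxel, the ratio

    S(q, Δ) / S(0, Δ) = exp(-K_α q² Δ^α),      q = γgδ/2π,

whose stretching exponent α (fitted over a Δ series, then averaged over
the x/y/z gradient directions to give Mα) equals 2/d_w. The stimulated-echo
T1 decay cancels in the ratio. Conventional mean diffusivity MD (trace/3
of a log-linearly fitted diffusion tensor, b0 + six directions) serves as
the Brownian control: it cannot distinguish matrices whose differences are
sub-resolution.

**Percolation calibration.** Across samples, Mα decays with the specific
pore surface area S (m²/g) as

    Mα(S) = (1 - Mα∞) exp(-S/σ) + Mα∞,      Mα∞ ≈ 2/3,

and d_w(S) = 2/Mα(S) is equivalently described by the Padé approximant
d_w = (2 + 2x + x²/6)/(1 + x/2 + x²/12), x = S/σ. On a 2D percolation
cluster at threshold d_w = 2.87 (α_c ≈ 0.70), so the critical surface area
follows from the calibrated relation: S_c = σ·ln[(1-Mα∞)/(α_c-Mα∞)]
= σ·ln 10 for Mα∞ = 2/3.

**Local porosity theory.** The complex permittivity ε*(ω) of the composite
solves the self-consistent mixing law

    ∫ (εwe*-ε*)/(εwe*+2ε*) λ(ϕ)μ(ϕ) dϕ + ∫ (εpe*-ε*)/(εpe*+2ε*) (1-λ(ϕ))μ(ϕ) dϕ = 0

with μ(ϕ) a truncated Gaussian (mean ϕ0, variance Var) and λ(ϕ) = ϕ^Γ the
local percolation probability. The forward solver (damped complex Newton
with frequency continuation) and the three-parameter inversion (Γ, ϕ0,
Var) are both provided.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (outputs under `results/`):

```sh
python analysis/01_simulate.py --seed 1   # three-sample phantoms + spectrum
python analysis/02_fit_maps.py            # Mα and MD maps, ROI stats
python analysis/03_calibrate.py           # Mα(S) fit, d_w table, S_c
python analysis/04_dielectric.py          # LPT inversion
```

Step 02 prints the ROI summaries and pairwise Cliff's delta. At seed 1 the
Mα medians are 0.982 (G80, S = 16 m²/g), 0.906 (G60, S = 100) and 0.845
(G40, S = 188) — strictly ordered by surface area, with
|delta| = 0.98 between G80 and G40 — while the MD medians are
statistically indistinguishable (|delta| ≤ 0.010): the anomalous exponent
sees the sub-micron structure, the Brownian diffusivity does not. Step 03
converts the medians to walk dimensions and calibrates the surface-area
relation:

```
label  S_m2_per_g  Malpha_median      d_w
  G80        16.0       0.982449 2.035728
  G60       100.0       0.906191 2.207040
  G40       188.0       0.845162 2.366410

All samples sit below the percolation threshold (S_c = 694 m^2/g, d_w < 2.87).
```

Step 04 recovers the dielectric generator's parameters (Γ = 2.0,
ϕ0 = 0.80, Var = 0.010) from the noiseless spectrum to machine precision.

The same pipeline is scriptable through the CLI (`porodiff simulate dwi`,
`porodiff fit maps`, `porodiff calibrate`, `porodiff dielectric fit`,
`porodiff report`) with JSON configs, seeded manifests and NIfTI/CSV/JSON
outputs.

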