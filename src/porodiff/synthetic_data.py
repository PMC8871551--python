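"""Seeded phantom and spectrum generators emulating the study's acquisitions.

Three kinds of synthetic inputs are produced:

* PGSTE diffusion-weighted image series of a circular sample in a 128×128,
  0.8 cm field of view, with per-voxel (α, K_α, D) fields, stimulated-echo
  T1 decay exp(-Δ/T1) common to all acquisitions (it cancels in the
  g>0 / g=0 ratio) and Rician magnitude noise at an NSA-32-equivalent level;
* three-sample scenarios keyed to the measured specific surface areas
  (G80: 16, G60: 100, G40: 188 m²/g), with sample-mean α set by the
  empirical relation Mα(S) = (1-Mα∞)exp(-S/σ) + Mα∞ and identical
  diffusivity across samples (so MD carries no sample information);
* calibration point sets from the same relation and complex permittivity
  spectra from the local-porosity-theory forward solver.

Every generator is driven by an integer seed; identical seed and spec give
bit-identical output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .containers import Acquisition, DWISeries
from .dielectric_lpt import DielectricSpectrum, LPTParams, forward_spectrum
from .signal_models import PGSTEProtocol, q_value

#: diffusivity of free water near 18 °C, m²/s
D_WATER = 2.0e-9
#: K_α matching Brownian water at α = 1 in the q = γgδ/2π convention,
#: where exp(-K q² Δ) must equal exp(-(2πq)² D Δ):  K = (2π)² D
K_WATER = (2.0 * np.pi) ** 2 * D_WATER

NSA = 32  # averaged scans; noise sd divided by sqrt(NSA)

#: decay constant of the Mα(S) relation consistent with S_c = σ ln10 ≈ 695 m²/g
SIGMA_DEFAULT = 301.8
MALPHA_INF_DEFAULT = 2.0 / 3.0

#: Table of (label, specific surface area m²/g) of the three matrices
SAMPLE_SURFACE_AREAS = (("G80", 16.0), ("G60", 100.0), ("G40", 188.0))


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent generator for a named pipeline stage under one global seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % (2**31), zlib.crc32(name.encode())])
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic sample phantom.

    ``roi_radius_frac`` is the sample radius as a fraction of the FOV
    (default 0.4375: a 7 mm cylinder centred in the 8 mm field of view).
    Voxel parameter fields are independent truncated normals; ``snr`` is the
    single-scan Rician signal-to-noise ratio at g = 0 and the shortest Δ
    (np.inf for a noiseless phantom).
    """

    matrix_size: int = 128
    fov: float = 0.008
    roi_radius_frac: float = 0.4375
    alpha_mean: float = 0.85
    alpha_sd: float = 0.04
    K_mean: float = K_WATER
    K_sd: float = 0.1 * K_WATER
    D_mean: float = D_WATER
    D_sd: float = 0.1e-9
    T1: float = 1.5
    snr: float = 50.0
    seed: int = 0

    def __post_init__(self):
        if self.snr <= 0:
            raise ValueError("snr must be > 0 (np.inf for noiseless)")
        if not 0 < self.roi_radius_frac <= 0.5:
            raise ValueError("roi_radius_frac must be in (0, 0.5]")


@dataclass
class ScenarioTable:
    """Per-sample records (label, surface area, phantom spec)."""

    records: list  # of (label, S, PhantomSpec)

    def __post_init__(self):
        labels = [r[0] for r in self.records]
        if len(set(labels)) != len(labels):
            raise ValueError("sample labels must be unique")
        if any(r[1] <= 0 for r in self.records):
            raise ValueError("surface areas must be positive")

    def to_records(self) -> list:
        return [
            {"label": lab, "S_m2_per_g": S, "alpha_mean": spec.alpha_mean,
             "alpha_sd": spec.alpha_sd, "D_mean": spec.D_mean, "snr": spec.snr,
             "seed": spec.seed}
            for lab, S, spec in self.records
        ]


def default_alpha_protocol(n_Delta: int = 8) -> PGSTEProtocol:
    """α-branch acquisition: log-spaced Δ in [20, 250] ms, x/y/z directions."""
    grid = tuple(np.geomspace(0.020, 0.250, n_Delta))
    return PGSTEProtocol(g=0.074, delta=0.002, Delta_grid=grid,
                         directions=((1.0, 0.0, 0.0), (0.0, 1.0, 0.0),
                                     (0.0, 0.0, 1.0)))


def default_md_protocol() -> PGSTEProtocol:
    """MD-branch acquisition: Δ = 100 ms, b0 plus six non-coplanar directions."""
    r = 1.0 / np.sqrt(2.0)
    dirs = ((r, r, 0.0), (r, 0.0, r), (0.0, r, r),
            (r, -r, 0.0), (r, 0.0, -r), (0.0, r, -r))
    return PGSTEProtocol(g=0.074, delta=0.002, Delta_grid=(0.100,),
                         directions=dirs)


def _truncated_field(rng, mean, sd, lo, hi, size):
    if sd == 0:
        return np.full(size, float(mean))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


def _roi_mask(matrix_size: int, radius_frac: float) -> np.ndarray:
    c = (matrix_size - 1) / 2.0
    yy, xx = np.mgrid[0:matrix_size, 0:matrix_size]
    r_vox = radius_frac * matrix_size
    return (yy - c) ** 2 + (xx - c) ** 2 <= r_vox**2


def _rician(rng, signal: np.ndarray, sigma: float) -> np.ndarray:
    n1 = rng.standard_normal(signal.shape)
    n2 = rng.standard_normal(signal.shape)
    return np.sqrt((signal + sigma * n1) ** 2 + (sigma * n2) ** 2)


def make_dwi_series(spec: PhantomSpec, protocol: PGSTEProtocol,
                    branch: str = "alpha") -> DWISeries:
    """Simulate a PGSTE diffusion-weighted series of a circular phantom.

    ``branch='alpha'`` drives the stretched-exponential model
    S = S0 exp(-Δ/T1) exp(-K_α q² Δ^α) for g > 0 (isotropic, identical in
    all directions); ``branch='md'`` drives the mono-exponential tensor
    model exp(-b D) at the single Δ of the protocol.  Per-voxel ground-truth
    maps are stored with the series.
    """
    if len(protocol.Delta_grid) < 3 and branch == "alpha":
        raise ValueError("alpha branch needs >= 3 diffusion times")
    n = spec.matrix_size
    roi = _roi_mask(n, spec.roi_radius_frac)
    n_in = int(roi.sum())

    rng = substream(spec.seed, f"phantom-{branch}")
    alpha = np.full((n, n), np.nan)
    K = np.full((n, n), np.nan)
    D = np.full((n, n), np.nan)
    alpha[roi] = _truncated_field(rng, spec.alpha_mean, spec.alpha_sd,
                                  0.1 + 1e-9, 1.2, n_in)
    K[roi] = _truncated_field(rng, spec.K_mean, spec.K_sd,
                              1e-12, np.inf, n_in)
    D[roi] = _truncated_field(rng, spec.D_mean, spec.D_sd,
                              1e-15, np.inf, n_in)

    S0 = 1.0
    q = q_value(protocol)
    delta_min = min(protocol.Delta_grid)
    sigma_noise = 0.0
    if np.isfinite(spec.snr):
        sigma_noise = S0 * np.exp(-delta_min / spec.T1) / spec.snr / np.sqrt(NSA)

    data, acqs = [], []
    for Delta in protocol.Delta_grid:
        t1_factor = np.exp(-Delta / spec.T1)
        base = np.where(roi, S0 * t1_factor, 0.0)
        # reference scan (g = 0)
        img = base.copy()
        if sigma_noise > 0:
            img = _rician(rng, img, sigma_noise)
        data.append(img)
        acqs.append(Acquisition(Delta=Delta, g=0.0, direction=(1.0, 0.0, 0.0)))
        for direction in protocol.directions:
            if branch == "alpha":
                att = np.exp(-np.nan_to_num(K) * q**2
                             * Delta ** np.nan_to_num(alpha, nan=1.0))
            elif branch == "md":
                gd = protocol.gamma * protocol.g * protocol.delta
                b = gd * gd * (Delta - protocol.delta / 3.0)
                att = np.exp(-b * np.nan_to_num(D))
            else:
                raise ValueError(f"unknown branch {branch!r}")
            img = base * np.where(roi, att, 0.0)
            if sigma_noise > 0:
                img = _rician(rng, img, sigma_noise)
            data.append(img)
            acqs.append(Acquisition(Delta=Delta, g=protocol.g,
                                    direction=tuple(direction)))

    return DWISeries(
        data=np.stack(data), acquisitions=acqs, fov=spec.fov,
        ground_truth={"alpha": alpha, "K_alpha": K, "D": D, "roi": roi},
    )


def malpha_of_surface_area(S, sigma: float = SIGMA_DEFAULT,
                           Malpha_inf: float = MALPHA_INF_DEFAULT):
    """Sample-mean Mα from the surface-area relation (generator-side copy)."""
    S = np.asarray(S, dtype=float)
    out = (1.0 - Malpha_inf) * np.exp(-S / sigma) + Malpha_inf
    return float(out) if out.ndim == 0 else out


def three_sample_scenario(sigma: float = SIGMA_DEFAULT,
                          Malpha_inf: float = MALPHA_INF_DEFAULT,
                          seed: int = 0, matrix_size: int = 128,
                          snr: float = 50.0) -> ScenarioTable:
    """G80/G60/G40 phantom specs with α means from the Mα(S) relation.

    Diffusivity is identical across samples by construction, so the MD map
    cannot discriminate them; only the α field differs.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if not 0 < Malpha_inf < 1:
        raise ValueError("Malpha_inf must be in (0, 1)")
    records = []
    for i, (label, S) in enumerate(SAMPLE_SURFACE_AREAS):
        sub = substream(seed, f"scenario-{label}")
        spec = PhantomSpec(
            matrix_size=matrix_size,
            alpha_mean=malpha_of_surface_area(S, sigma, Malpha_inf),
            snr=snr,
            seed=int(sub.integers(2**31)),
        )
        records.append((label, S, spec))
    return ScenarioTable(records=records)


def make_calibration_points(sigma: float, Malpha_inf: float, S_list,
                            noise_sd: float = 0.0, seed: int = 0) -> np.ndarray:
    """(S, Mα) pairs from the empirical relation with optional Gaussian noise."""
    S = np.asarray(S_list, dtype=float)
    if np.any(S < 0):
        raise ValueError("S must be >= 0")
    rng = substream(seed, "calibration-points")
    M = malpha_of_surface_area(S, sigma, Malpha_inf)
    if noise_sd > 0:
        M = M + noise_sd * rng.standard_normal(S.shape)
    M = np.clip(M, 1e-9, 1.2)
    return np.column_stack([S, M])


def make_dielectric_spectrum(lpt: LPTParams, freqs, noise_frac: float = 0.0,
                             seed: int = 0) -> DielectricSpectrum:
    """Forward LPT spectrum with optional multiplicative Gaussian noise."""
    clean = forward_spectrum(lpt, freqs)
    if noise_frac == 0:
        return clean
    rng = substream(seed, "dielectric-spectrum")
    re = clean.eps_real * (1 + noise_frac * rng.standard_normal(clean.freqs.size))
    im = clean.eps_loss * (1 + noise_frac * rng.standard_normal(clean.freqs.size))
    re = np.clip(re, 1e-12, None)
    im = np.clip(im, 0.0, None)
    return DielectricSpectrum(freqs=clean.freqs, eps_complex=re - 1j * im)
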