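"""Walk dimension, the Mα-surface-area calibration and percolation scaling.

The voxel-averaged anomalous exponent Mα maps onto the walk dimension of the
underlying random walk through d_w = 2/Mα.  Across samples, Mα decays with
the specific pore surface area S (the obstacle-concentration proxy) as

    Mα(S) = (1 - Mα∞) exp(-S/σ) + Mα∞,

with plateau Mα∞ ≈ 2/3.  Percolation theory fixes the threshold values
d_w = 2.87 and α_c ≈ 0.70 for diffusion on the incipient infinite cluster in
2D, so the critical surface area is read off at Mα = α_c:

    S_c = σ ln[(1 - Mα∞)/(α_c - Mα∞)]     (= σ ln 10 for Mα∞ = 2/3).

A Padé approximant d_w(x) = (2 + 2x + x²/6)/(1 + x/2 + x²/12), x = S/σ,
matches 2/Mα(S) over the measured range; the crossover length between the
fractal and homogeneous diffusion regimes diverges near threshold as
|C - C_c|^-(ν + β/2) with 2D exponents ν = 4/3, β = 5/36.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize


@dataclass(frozen=True)
class PercolationConstants:
    """2D percolation exponents and threshold walk dimension."""

    nu: float = 4.0 / 3.0           # correlation-length exponent
    beta: float = 5.0 / 36.0        # order-parameter exponent
    dw_threshold: float = 2.87      # walk dimension at threshold
    alpha_threshold: float = 0.70   # anomalous exponent at threshold

    def __post_init__(self):
        if abs(self.alpha_threshold * self.dw_threshold - 2.0) > 0.01:
            raise ValueError("alpha_threshold * dw_threshold must be ~2")

    @property
    def crossover_exponent(self) -> float:
        """ν + β/2 (= 101/72 ≈ 1.4028 in 2D)."""
        return self.nu + self.beta / 2.0


def dw_from_alpha(alpha):
    """Walk dimension d_w = 2/α."""
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("alpha must be > 0")
    out = 2.0 / alpha
    return float(out) if out.ndim == 0 else out


def alpha_from_dw(d_w):
    """Anomalous exponent α = 2/d_w (inverse of dw_from_alpha)."""
    d_w = np.asarray(d_w, dtype=float)
    if np.any(d_w <= 0):
        raise ValueError("d_w must be > 0")
    out = 2.0 / d_w
    return float(out) if out.ndim == 0 else out


@dataclass
class CalibrationFit:
    """Fitted parameters of the Mα(S) relation."""

    Malpha_inf: float
    sigma: float
    covariance: np.ndarray | None = None
    residuals: np.ndarray | None = None

    def __post_init__(self):
        if not 0 < self.Malpha_inf < 1:
            raise ValueError("Malpha_inf must be in (0, 1)")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


def empirical_relation(S, fit: CalibrationFit):
    """Mα(S) = (1 - Mα∞) exp(-S/σ) + Mα∞, strictly decreasing in S."""
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValueError("S must be >= 0")
    out = (1.0 - fit.Malpha_inf) * np.exp(-S / fit.sigma) + fit.Malpha_inf
    return float(out) if out.ndim == 0 else out


def dw_curve(S, fit: CalibrationFit):
    """d_w(S) = 2/Mα(S), increasing from 2 towards 2/Mα∞."""
    return dw_from_alpha(empirical_relation(S, fit))


def fit_empirical_relation(points, fix_plateau: float | None = None,
                           include_anchor: bool = True) -> CalibrationFit:
    """Least-squares fit of (σ, Mα∞) — or σ alone — to (S, Mα) points.

    The free-water anchor (S = 0, Mα = 1) is appended by default unless a
    point at S = 0 is already present.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if include_anchor and not np.any(pts[:, 0] == 0):
        pts = np.vstack([[0.0, 1.0], pts])
    S, M = pts[:, 0], pts[:, 1]
    if np.unique(S).size < S.size:
        raise ValueError("S values must be distinct")
    n_free = 1 if fix_plateau is not None else 2
    if S.size < n_free + 1:
        raise ValueError(f"need >= {n_free + 1} points")

    span = max(S.max(), 1.0)
    if fix_plateau is not None:
        def model(S, sigma):
            return (1 - fix_plateau) * np.exp(-S / sigma) + fix_plateau
        p0 = [span / 2]
        popt, pcov = optimize.curve_fit(model, S, M, p0=p0,
                                        bounds=([1e-12], [np.inf]),
                                        xtol=1e-15, ftol=1e-15, gtol=1e-15,
                                        maxfev=10000)
        minf, sigma = fix_plateau, float(popt[0])
    else:
        def model(S, minf, sigma):
            return (1 - minf) * np.exp(-S / sigma) + minf
        p0 = [max(min(M.min(), 0.9), 0.1), span / 2]
        popt, pcov = optimize.curve_fit(model, S, M, p0=p0,
                                        bounds=([1e-9, 1e-12], [1 - 1e-9, np.inf]),
                                        xtol=1e-15, ftol=1e-15, gtol=1e-15,
                                        maxfev=10000)
        minf, sigma = float(popt[0]), float(popt[1])
        if minf < 1e-6 or minf > 1 - 1e-6:
            warnings.warn("plateau estimate pinned at its bound", stacklevel=2)
            minf = float(np.clip(minf, 1e-6, 1 - 1e-6))

    fit = CalibrationFit(Malpha_inf=minf, sigma=sigma, covariance=pcov)
    fit.residuals = M - empirical_relation(S, fit)
    return fit


def critical_surface_area(fit: CalibrationFit, alpha_c: float = 0.70) -> float:
    """Surface area S_c at which Mα(S) crosses the percolation threshold α_c.

    S_c = σ ln[(1 - Mα∞)/(α_c - Mα∞)]; undefined when the plateau lies at or
    above the threshold (the relation then never reaches α_c).
    """
    if fit.Malpha_inf >= alpha_c:
        raise ValueError("plateau above threshold: Mα(S) never reaches alpha_c")
    return fit.sigma * float(np.log((1 - fit.Malpha_inf) / (alpha_c - fit.Malpha_inf)))


def pade_dw(x):
    """Padé approximant d_w(x) = (2 + 2x + x²/6)/(1 + x/2 + x²/12), x = S/σ."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("x must be >= 0")
    out = (2.0 + 2.0 * x + x**2 / 6.0) / (1.0 + x / 2.0 + x**2 / 12.0)
    return float(out) if out.ndim == 0 else out


def crossover_scaling(C, C_c, constants: PercolationConstants | None = None):
    """Relative crossover length l_max ~ |C - C_c|^-(ν + β/2).

    Returns the pure power law (prefactor 1); diverges at C = C_c.
    """
    constants = constants or PercolationConstants()
    C = np.asarray(C, dtype=float)
    dist = np.abs(C - C_c)
    if np.any(dist == 0):
        raise ZeroDivisionError("crossover length diverges at C = C_c")
    out = dist ** (-constants.crossover_exponent)
    return float(out) if out.ndim == 0 else out
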