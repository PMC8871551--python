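"""Local porosity theory (LPT) dielectric mixing law: forward solve and inversion.

A water-saturated porous polymer is described by two geometric functions of
the local porosity ϕ measured in a mesoscopic measurement cell:

* ``μ(ϕ)`` — the local porosity distribution, here a Gaussian with mean
  ``ϕ0`` and variance ``Var`` truncated to [0, 1] and renormalised;
* ``λ(ϕ) = ϕ^Γ`` — the local percolation probability, the fraction of cells
  of porosity ϕ whose pore space percolates.

The effective complex permittivity ε*(ω) of the composite solves the
self-consistent mixing integral

    ∫ (εwe*-ε*)/(εwe*+2ε*) λ(ϕ) μ(ϕ) dϕ
  + ∫ (εpe*-ε*)/(εpe*+2ε*) (1-λ(ϕ)) μ(ϕ) dϕ = 0,

where εwe*(ϕ, ω) and εpe*(ϕ, ω) are Maxwell-Garnett-type effective
permittivities of a percolating (water-connected) and a blocked
(polymer-connected) cell of porosity ϕ.  The internal sign convention is
ε* = ε' - iε'' with ε'' >= 0, so physical (lossy) roots have Im ε* <= 0.

The inverse problem fits the three free parameters (Γ, ϕ0, Var) to a
measured or synthetic spectrum, the component properties (εw, σw, εp) being
known.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy import optimize

EPS0 = 8.8541878128e-12  # vacuum permittivity, F/m

N_QUAD = 128
RESIDUAL_TOL = 1e-10
#: variance below which μ(ϕ) is treated as a point mass at ϕ0
DELTA_VAR = 1e-12


class SolverFailure(RuntimeError):
    """Raised when no root of the mixing law is found at some frequency."""


@lru_cache(maxsize=16)
def _leggauss01(n: int):
    """Gauss-Legendre nodes/weights on [0, 1] (cached; treat as read-only)."""
    x, w = leggauss(n)
    return 0.5 * (x + 1.0), 0.5 * w


@dataclass(frozen=True)
class LPTParams:
    """Local-porosity-theory parameters and component permittivities.

    Gamma    : exponent of the percolation probability λ(ϕ) = ϕ^Γ
    phi0     : mean of the local porosity distribution
    var      : variance of the local porosity distribution
    eps_w    : relative permittivity of the aqueous phase
    sigma_w  : conductivity of the aqueous phase, S/m
    eps_p    : relative permittivity of the polymer (frequency independent;
               the polymer conductivity is taken as zero)
    """

    Gamma: float = 2.0
    phi0: float = 0.8
    var: float = 0.01
    eps_w: float = 78.5
    sigma_w: float = 0.1
    eps_p: float = 3.0
    eps0: float = EPS0

    def __post_init__(self):
        if self.Gamma < 0:
            raise ValueError("Gamma must be >= 0")
        if not 0 < self.phi0 < 1:
            raise ValueError("phi0 must be in (0, 1)")
        if self.var < 0:
            raise ValueError("var must be >= 0")
        if self.sigma_w < 0:
            raise ValueError("sigma_w must be >= 0")


@dataclass
class DielectricSpectrum:
    """Complex permittivity spectrum in the ε* = ε' - iε'' convention."""

    freqs: np.ndarray
    eps_complex: np.ndarray

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.eps_complex = np.asarray(self.eps_complex, dtype=complex)
        if self.freqs.size != self.eps_complex.size:
            raise ValueError("freqs and eps_complex length mismatch")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly ascending")
        if np.any(self.eps_complex.real <= 0):
            raise ValueError("real permittivity must be positive")

    @property
    def eps_real(self) -> np.ndarray:
        return self.eps_complex.real

    @property
    def eps_loss(self) -> np.ndarray:
        """Dielectric loss ε'' (positive for lossy media)."""
        return -self.eps_complex.imag


def water_eps(freq, params: LPTParams):
    """Complex water permittivity εw* = εw - i σw/(ε0 ω), ω = 2πf."""
    freq = np.asarray(freq, dtype=float)
    if np.any(freq <= 0):
        raise ValueError("frequency must be > 0")
    omega = 2.0 * np.pi * freq
    out = np.asarray(params.eps_w - 1j * params.sigma_w / (params.eps0 * omega))
    return complex(out) if out.ndim == 0 else out


def effective_component_eps(phi, freq, params: LPTParams):
    """Effective permittivities (εwe*, εpe*) of a cell with local porosity ϕ.

    The percolating-cell value εwe* interpolates from εp* at ϕ = 0 to εw* at
    ϕ = 1; the blocked-cell value εpe* runs the same limits the other way
    round (a cell of porosity 1 is pure water, of porosity 0 pure polymer).
    """
    phi = np.asarray(phi, dtype=float)
    if np.any((phi < 0) | (phi > 1)):
        raise ValueError("phi must lie in [0, 1]")
    ew = water_eps(freq, params)
    ep = complex(params.eps_p)

    den_w = 1.0 / (1.0 - ep / ew) - phi / 3.0
    den_p = 1.0 / (1.0 - ew / ep) - (1.0 - phi) / 3.0
    small_w = np.abs(den_w) < 1e-12
    small_p = np.abs(den_p) < 1e-12
    if np.any(small_w) or np.any(small_p):
        warnings.warn("near-singular denominator; perturbing phi by 1e-9",
                      stacklevel=2)
        phi = np.where(small_w | small_p, phi + 1e-9, phi)
        den_w = 1.0 / (1.0 - ep / ew) - phi / 3.0
        den_p = 1.0 / (1.0 - ew / ep) - (1.0 - phi) / 3.0

    eps_we = ew * (1.0 - (1.0 - phi) / den_w)
    eps_pe = ep * (1.0 - phi / den_p)
    return eps_we, eps_pe


def porosity_nodes(params: LPTParams, n_nodes: int = N_QUAD):
    """Quadrature nodes and μ-weights on [0, 1] for the truncated Gaussian.

    Returns (phi_nodes, weights) with weights summing to 1 exactly (the
    truncated density is renormalised on the quadrature rule), so that
    ``sum(w * f(phi))`` approximates ``∫ f(ϕ) μ(ϕ) dϕ``.
    """
    if params.var <= DELTA_VAR:
        return np.array([params.phi0]), np.array([1.0])
    phi, w = _leggauss01(n_nodes)
    sd = np.sqrt(params.var)
    # unnormalised Gaussian kernel; the truncation/normalisation constant
    # cancels in the quadrature renormalisation below
    pdf = np.exp(-0.5 * ((phi - params.phi0) / sd) ** 2)
    mu_w = w * pdf
    total = mu_w.sum()
    if total <= 0:
        raise ValueError("degenerate porosity distribution")
    return phi, mu_w / total


def bulk_porosity(params: LPTParams, n_nodes: int = N_QUAD) -> float:
    """Bulk porosity Φ = ∫ ϕ μ(ϕ) dϕ (water volume fraction)."""
    phi, w = porosity_nodes(params, n_nodes)
    return float((w * phi).sum())


def local_percolation_probability(phi, params: LPTParams):
    """λ(ϕ) = ϕ^Γ."""
    return np.asarray(phi, dtype=float) ** params.Gamma


def _residual_terms(eps, phi, mu_w, eps_we, eps_pe, lam):
    den_w = eps_we + 2.0 * eps
    den_p = eps_pe + 2.0 * eps
    if np.any(np.abs(den_w) < 1e-14) or np.any(np.abs(den_p) < 1e-14):
        raise SolverFailure("pole in integrand: component eps + 2*eps ~ 0")
    f = (mu_w * (lam * (eps_we - eps) / den_w
                 + (1 - lam) * (eps_pe - eps) / den_p)).sum()
    # d/dε of (a-ε)/(a+2ε) is -3a/(a+2ε)²
    df = (mu_w * (lam * (-3.0 * eps_we) / den_w**2
                  + (1 - lam) * (-3.0 * eps_pe) / den_p**2)).sum()
    return f, df


def mixing_residual(eps_trial: complex, freq: float, params: LPTParams,
                    n_nodes: int = N_QUAD) -> complex:
    """Value of the self-consistent mixing integral at a trial ε*."""
    if np.real(eps_trial) <= 0:
        raise ValueError("trial eps must have positive real part")
    phi, mu_w = porosity_nodes(params, n_nodes)
    eps_we, eps_pe = effective_component_eps(phi, freq, params)
    lam = local_percolation_probability(phi, params)
    f, _ = _residual_terms(complex(eps_trial), phi, mu_w, eps_we, eps_pe, lam)
    return f


def _initial_guess(freq, params: LPTParams):
    lam0 = params.phi0 ** params.Gamma
    eps_we0, eps_pe0 = effective_component_eps(params.phi0, freq, params)
    return lam0 * eps_we0 + (1 - lam0) * eps_pe0


def _grid_scan_start(phi, mu_w, eps_we, eps_pe, lam, freq, params,
                     grid: int = 41, levels: int = 4) -> complex:
    """Coarse |residual| minimisation on a complex-plane grid.

    Last-resort start generator when Newton stalls from all analytic
    guesses (the low-loss roots of barely-percolating media sit far from
    the λ-mixture seed).
    """
    g = _initial_guess(freq, params)
    wat = water_eps(freq, params)
    re_lo = min(params.eps_p * 0.3, 1e-2)
    re_hi = abs(g.real) * 3 + params.eps_w * 3
    im_lo, im_hi = 0.0, abs(g.imag) * 3 + abs(wat.imag) * 1.5 + 1.0
    best = g
    for _ in range(levels):
        re = np.linspace(re_lo, re_hi, grid)
        im = np.linspace(im_lo, im_hi, grid)
        RE, IM = np.meshgrid(re, im)
        E = RE - 1j * IM
        den_w = eps_we[None, None, :] + 2 * E[..., None]
        den_p = eps_pe[None, None, :] + 2 * E[..., None]
        with np.errstate(divide="ignore", invalid="ignore"):
            F = (mu_w * (lam * (eps_we - E[..., None]) / den_w
                         + (1 - lam) * (eps_pe - E[..., None]) / den_p)).sum(-1)
        F = np.where(np.isfinite(F), F, np.inf)
        k = np.unravel_index(np.argmin(np.abs(F)), F.shape)
        best = E[k]
        dre, dim = re[1] - re[0], im[1] - im[0]
        re_lo, re_hi = max(best.real - 2 * dre, 1e-12), best.real + 2 * dre
        im_lo = max(-best.imag - 2 * dim, 0.0)
        im_hi = -best.imag + 2 * dim
    return best


def solve_effective_eps(freq: float, params: LPTParams, guess=None,
                        n_nodes: int = N_QUAD, max_iter: int = 100,
                        n_restarts: int = 10) -> complex:
    """Root ε*(ω) of the mixing law on the lossy branch (Im ε* <= 0).

    Damped complex Newton iteration with analytic derivative; the starting
    point defaults to the μ-weighted λ-mixture of the two effective
    component permittivities at ϕ0 (or a continuation seed from the
    previous frequency).  Seeded random restarts perturb the guess if the
    iteration stalls.
    """
    phi, mu_w = porosity_nodes(params, n_nodes)
    eps_we, eps_pe = effective_component_eps(phi, freq, params)
    lam = local_percolation_probability(phi, params)
    if guess is None:
        guess = _initial_guess(freq, params)

    def newton_from(start: complex):
        eps = complex(start)
        if eps.real <= 0:
            eps = abs(eps.real) + 1e-6 + 1j * eps.imag
        if eps.imag > 0:
            eps = eps.real - 1j * abs(eps.imag)
        try:
            f, df = _residual_terms(eps, phi, mu_w, eps_we, eps_pe, lam)
        except SolverFailure:
            return None
        for _ in range(max_iter):
            if abs(f) < RESIDUAL_TOL:
                return eps
            if df == 0:
                return None
            step = -f / df
            t = 1.0
            for _bt in range(60):  # backtracking keeping Re ε > 0
                trial = eps + t * step
                if trial.real > 0:
                    try:
                        f_t, df_t = _residual_terms(
                            trial, phi, mu_w, eps_we, eps_pe, lam)
                    except SolverFailure:
                        f_t = None
                    if f_t is not None and abs(f_t) < abs(f):
                        eps, f, df = trial, f_t, df_t
                        break
                t *= 0.5
            else:
                return None
        return eps if abs(f) < RESIDUAL_TOL else None

    # deterministic starts: continuation/mixture guess, then the two
    # component-dominated limits
    eps_we0, eps_pe0 = effective_component_eps(params.phi0, freq, params)
    starts = [complex(guess), eps_we0, eps_pe0]
    rng = np.random.default_rng(0)
    for _ in range(n_restarts):
        scale = 1.0 + 0.5 * rng.standard_normal()
        starts.append(complex(guess) * scale
                      - 1j * abs(complex(guess)) * rng.random())
    for start in starts:
        root = newton_from(start)
        if root is not None:
            return root
    # last resort: locate the basin by a coarse grid scan, then polish
    root = newton_from(_grid_scan_start(phi, mu_w, eps_we, eps_pe, lam,
                                        freq, params))
    if root is not None:
        return root
    raise SolverFailure(f"no root with |residual| < {RESIDUAL_TOL} at "
                        f"freq = {freq:.6g} Hz")


def forward_spectrum(params: LPTParams, freqs, n_nodes: int = N_QUAD) -> DielectricSpectrum:
    """ε*(ω) over a frequency grid, with frequency continuation.

    Each frequency's root seeds the Newton solve at the next; the first
    frequency starts from the λ-mixture guess.
    """
    freqs = np.asarray(freqs, dtype=float)
    if np.any(np.diff(freqs) <= 0):
        raise ValueError("freqs must be strictly ascending")
    out = np.empty(freqs.size, dtype=complex)
    seed = None
    for i, f in enumerate(freqs):
        try:
            out[i] = solve_effective_eps(f, params, guess=seed, n_nodes=n_nodes)
        except SolverFailure as err:
            raise SolverFailure(f"frequency index {i}: {err}") from err
        seed = out[i]
    return DielectricSpectrum(freqs=freqs, eps_complex=out)


def default_frequency_grid(n: int = 50, f_min: float = 1e3,
                           f_max: float = 2e9) -> np.ndarray:
    """Log-spaced measurement grid, 1 kHz - 2 GHz by default."""
    return np.logspace(np.log10(f_min), np.log10(f_max), n)


FIT_BOUNDS = ((0.0, 0.011, 0.0), (20.0, 0.989, 0.25))


def fit_lpt(spectrum: DielectricSpectrum, known: LPTParams | None = None,
            n_starts: int = 5, seed: int = 0, n_nodes: int = N_QUAD):
    """Fit (Γ, ϕ0, Var) to a permittivity spectrum by multistart least squares.

    ``known`` carries the fixed component properties (εw, σw, εp); only the
    three geometric parameters are free.  The objective is the relative
    misfit of real part and loss, stacked over frequencies.

    Returns (LPTParams, diagnostics) where diagnostics holds the residual
    norm, per-frequency residuals and the number of successful starts.
    """
    if spectrum.freqs.size < 10:
        raise ValueError("need >= 10 frequencies")
    if np.log10(spectrum.freqs[-1] / spectrum.freqs[0]) < 3:
        raise ValueError("need >= 3 decades of frequency coverage")
    base = known if known is not None else LPTParams()

    w_re = np.abs(spectrum.eps_real)
    w_im = np.maximum(np.abs(spectrum.eps_loss), 1e-3 * w_re)

    def residuals(theta):
        gamma, phi0, var = theta
        p = replace(base, Gamma=gamma, phi0=phi0, var=var)
        model = forward_spectrum(p, spectrum.freqs, n_nodes=n_nodes)
        return np.concatenate([
            (model.eps_real - spectrum.eps_real) / w_re,
            (model.eps_loss - spectrum.eps_loss) / w_im,
        ])

    rng = np.random.default_rng(seed)
    lo = np.array(FIT_BOUNDS[0])
    hi = np.array(FIT_BOUNDS[1])
    starts = [np.array([2.0, 0.8, 0.02])]
    while len(starts) < n_starts:
        starts.append(lo + (hi - lo) * rng.random(3) * 0.9 + 0.05 * (hi - lo))

    best = None
    n_ok = 0
    for x0 in starts:
        try:
            sol = optimize.least_squares(residuals, x0, bounds=FIT_BOUNDS,
                                         xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except (SolverFailure, ValueError):
            continue
        n_ok += 1
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise SolverFailure("all fit starts failed")

    gamma, phi0, var = best.x
    fitted = replace(base, Gamma=float(gamma), phi0=float(phi0), var=float(var))
    diagnostics = {
        "cost": float(best.cost),
        "residual_norm": float(np.linalg.norm(best.fun)),
        "residuals": best.fun,
        "n_successful_starts": n_ok,
    }
    return fitted, diagnostics
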