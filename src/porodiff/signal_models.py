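"""Closed-form diffusion NMR signal models and wavevector/b-value arithmetic.

The pulsed-gradient stimulated-echo (PGSTE) experiment encodes molecular
displacement with two gradient pulses of strength ``g`` and duration ``delta``
separated by the diffusion time ``Delta``.  Two signal models are used
throughout the package:

* the mono-exponential (Brownian) decay ``S/S0 = exp(-b D)`` with the
  Stejskal-Tanner b-value ``b = (γ g δ)² (Δ - δ/3)``;
* the stretched-exponential subdiffusion decay
  ``S(q, Δ)/S(0, Δ) = exp(-K_α q² Δ^α)`` with wavevector ``q = γ g δ / 2π``,
  anomalous exponent ``α`` and generalized diffusion constant ``K_α``
  (units m²·s^-α in this q convention).

For ``α = 1`` the stretched model reduces to an ordinary exponential; the
walk dimension of the underlying random walk is ``d_w = 2/α``, with
``MSD ∝ t^(2/d_w)``.

All quantities are SI internally (m, s, T, rad); unit conversion belongs to
the I/O layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

#: Gyromagnetic ratio of the water proton, rad s^-1 T^-1.
GAMMA_PROTON = 2.6752e8


class InvalidProtocolError(ValueError):
    """Raised when acquisition parameters are unphysical."""


@dataclass(frozen=True)
class PGSTEProtocol:
    """Acquisition parameters of a PGSTE diffusion-weighted series.

    Parameters
    ----------
    gamma : float
        Gyromagnetic ratio, rad s^-1 T^-1.
    g : float
        Diffusion gradient strength, T m^-1 (0 for the reference scan).
    delta : float
        Gradient pulse duration δ, s.
    Delta_grid : tuple of float
        Diffusion times Δ, s; strictly increasing, at least 3 values so the
        anomalous exponent is identifiable.
    directions : tuple of 3-vectors
        Unit gradient directions.
    TE : float
        Echo time, s (metadata only).
    TR_base : float
        The repetition time follows TR = TR_base - Δ (metadata only).
    """

    gamma: float = GAMMA_PROTON
    g: float = 0.074
    delta: float = 0.002
    Delta_grid: tuple = ()
    directions: tuple = ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0))
    TE: float = 0.015
    TR_base: float = 5.0

    def __post_init__(self):
        if self.g < 0 or self.delta <= 0 or self.gamma <= 0:
            raise InvalidProtocolError(
                f"need gamma>0, g>=0, delta>0; got gamma={self.gamma}, "
                f"g={self.g}, delta={self.delta}"
            )
        grid = np.asarray(self.Delta_grid, dtype=float)
        if grid.size:
            if np.any(grid <= 0):
                raise InvalidProtocolError("all diffusion times must be > 0")
            if grid.size > 1 and np.any(np.diff(grid) <= 0):
                raise InvalidProtocolError("Delta grid must be strictly increasing")
            if np.any(grid < 5 * self.delta):
                warnings.warn(
                    "Delta < 5*delta violates the narrow-pulse condition Δ >> δ",
                    stacklevel=2,
                )
        for d in self.directions:
            n = float(np.linalg.norm(d))
            if abs(n - 1.0) > 1e-9:
                raise InvalidProtocolError(f"direction {d} is not unit-norm ({n})")

    def to_dict(self) -> dict:
        return {
            "gamma": self.gamma,
            "g_T_per_m": self.g,
            "delta_s": self.delta,
            "Delta_grid_s": list(self.Delta_grid),
            "directions": [list(d) for d in self.directions],
            "TE_s": self.TE,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PGSTEProtocol":
        return cls(
            gamma=d["gamma"],
            g=d["g_T_per_m"],
            delta=d["delta_s"],
            Delta_grid=tuple(d["Delta_grid_s"]),
            directions=tuple(tuple(x) for x in d["directions"]),
            TE=d.get("TE_s", 0.015),
        )


@dataclass(frozen=True)
class SubdiffusionParams:
    """Anomalous exponent α and generalized diffusion constant K_α."""

    alpha: float
    K_alpha: float

    def __post_init__(self):
        if not 0 < self.alpha <= 1.5:
            raise ValueError(f"alpha must be in (0, 1.5], got {self.alpha}")
        if self.K_alpha <= 0:
            raise ValueError(f"K_alpha must be > 0, got {self.K_alpha}")


@dataclass(frozen=True)
class MSDLaw:
    """Power-law mean-squared displacement, MSD = prefactor * t^(2/d_w)."""

    d_w: float
    prefactor: float

    def __post_init__(self):
        if self.d_w < 2:
            raise ValueError(f"d_w must be >= 2 for sub/normal diffusion, got {self.d_w}")
        if self.prefactor <= 0:
            raise ValueError("prefactor must be > 0")


def q_value(protocol: PGSTEProtocol) -> float:
    """Diffusion wavevector magnitude q = γ g δ / 2π, in m^-1."""
    return protocol.gamma * protocol.g * protocol.delta / (2.0 * np.pi)


def b_value(protocol: PGSTEProtocol, Delta) -> np.ndarray | float:
    """Stejskal-Tanner diffusion weighting b = (γ g δ)² (Δ - δ/3), in s m^-2.

    A warning is recorded if Δ < 5δ (the narrow-pulse assumption degrades);
    the computation still proceeds.
    """
    Delta = np.asarray(Delta, dtype=float)
    if np.any(Delta < 5 * protocol.delta):
        warnings.warn("Delta < 5*delta: b-value expression assumes Δ >> δ", stacklevel=2)
    gd = protocol.gamma * protocol.g * protocol.delta
    out = gd * gd * (Delta - protocol.delta / 3.0)
    return float(out) if out.ndim == 0 else out


def stretched_attenuation(params: SubdiffusionParams, q, Delta):
    """Stretched-exponential attenuation exp(-K_α q² Δ^α) of the g>0/g=0 ratio."""
    q = np.asarray(q, dtype=float)
    Delta = np.asarray(Delta, dtype=float)
    if np.any(q < 0):
        raise ValueError("q must be >= 0")
    if np.any(Delta <= 0):
        raise ValueError("Delta must be > 0")
    out = np.exp(-params.K_alpha * q**2 * Delta**params.alpha)
    return float(out) if out.ndim == 0 else out


def mono_attenuation(D: float, b):
    """Mono-exponential (Brownian) attenuation exp(-b D)."""
    if D <= 0:
        raise ValueError(f"D must be > 0, got {D}")
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("b must be >= 0")
    out = np.exp(-b * D)
    return float(out) if out.ndim == 0 else out


def msd(law: MSDLaw, t):
    """Mean-squared displacement prefactor * t^(2/d_w); linear in t iff d_w = 2."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("t must be > 0")
    out = law.prefactor * t ** (2.0 / law.d_w)
    return float(out) if out.ndim == 0 else out


#: Threshold on K_α q² Δ^α below which the low-q asymptotic signal model is
#: taken as valid (attenuation stays within one e-fold).
ASYMPTOTIC_THRESHOLD = 1.0


def asymptotic_validity(params: SubdiffusionParams, q, Delta):
    """True where the low-q condition K_α q² Δ^α <= 1 holds."""
    q = np.asarray(q, dtype=float)
    Delta = np.asarray(Delta, dtype=float)
    out = params.K_alpha * q**2 * Delta**params.alpha <= ASYMPTOTIC_THRESHOLD
    return bool(out) if out.ndim == 0 else out
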