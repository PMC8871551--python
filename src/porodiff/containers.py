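"""In-memory containers shared by the simulator and the map-fitting engine."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Acquisition:
    """Metadata of one diffusion-weighted image in a series."""

    Delta: float          # diffusion time, s
    g: float              # gradient strength, T/m (0 for the reference scan)
    direction: tuple      # unit gradient direction (meaningless when g == 0)


@dataclass
class DWISeries:
    """A stack of 2D magnitude images indexed by (Δ, g on/off, direction).

    ``data[k]`` is the image of ``acquisitions[k]``.  Geometry follows the
    microimaging protocol: square matrix, field of view ``fov`` (m), voxel
    size ``fov / matrix``.  ``ground_truth`` optionally carries the per-voxel
    (alpha, K_alpha, D) maps a phantom was generated from.
    """

    data: np.ndarray                  # (n_acq, ny, nx), magnitudes >= 0
    acquisitions: list
    fov: float
    slice_thickness: float = 1e-3
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.data.ndim != 3 or self.data.shape[0] != len(self.acquisitions):
            raise ValueError("data must be (n_acq, ny, nx) matching acquisitions")
        if np.any(self.data < 0):
            raise ValueError("magnitude data must be non-negative")
        # every diffusion-weighted image needs a same-Δ reference scan
        deltas_b0 = {a.Delta for a in self.acquisitions if a.g == 0}
        for a in self.acquisitions:
            if a.g > 0 and a.Delta not in deltas_b0:
                raise ValueError(f"no g=0 reference acquisition at Delta={a.Delta}")

    @property
    def matrix(self) -> int:
        return self.data.shape[1]

    @property
    def voxel_size(self) -> float:
        return self.fov / self.matrix

    def select(self, *, g=None, Delta=None, direction=None) -> list:
        """Indices of acquisitions matching the given criteria."""
        out = []
        for k, a in enumerate(self.acquisitions):
            if g is not None and not np.isclose(a.g, g):
                continue
            if Delta is not None and not np.isclose(a.Delta, Delta):
                continue
            if direction is not None and not np.allclose(a.direction, direction):
                continue
            out.append(k)
        return out


@dataclass
class ParameterMap:
    """A per-voxel fitted scalar with a validity mask and fit diagnostics."""

    values: np.ndarray        # (ny, nx) float; NaN where masked
    mask: np.ndarray          # (ny, nx) bool, True = valid
    diagnostics: dict = field(default_factory=dict)
    units: str = ""

    def __post_init__(self):
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        self.values = np.where(self.mask, self.values, np.nan)

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]


@dataclass
class ROIDistribution:
    """Values of a parameter map inside a circular region of interest."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise ValueError("empty ROI")

    @property
    def median(self) -> float:
        return float(np.median(self.values))

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def iqr(self) -> float:
        q1, q3 = np.percentile(self.values, [25, 75])
        return float(q3 - q1)

    @property
    def count(self) -> int:
        return int(self.values.size)

    def summary(self) -> dict:
        return {
            "n": self.count,
            "median": self.median,
            "mean": self.mean,
            "iqr": self.iqr,
        }
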