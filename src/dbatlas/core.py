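"""Core containers shared across the pipeline.

Coordinate convention: pixel (row, col) has its centre at
``x = col * spacing``, ``y = row * spacing`` (mm, 0-based). Landmark files
and all landmark arrays are in mm as (x, y) pairs.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

N_LANDMARKS = 65
AGE_SUPPORT = (20.0, 97.0)


class ConfigurationError(ValueError):
    """A configuration violates a structural precondition."""


class CoverageError(RuntimeError):
    """Too few valid template pixels to compute an unbiased statistic."""


class RegistrationError(RuntimeError):
    """The thin-plate-spline system is singular or degenerate."""


def as_landmarks(points) -> np.ndarray:
    """Validate and return a (65, 2) float array of landmark mm coordinates."""
    pts = np.asarray(points, dtype=float)
    if pts.shape != (N_LANDMARKS, 2):
        raise ConfigurationError(
            f"expected {N_LANDMARKS} (x, y) landmarks, got shape {pts.shape}"
        )
    if not np.all(np.isfinite(pts)):
        raise ConfigurationError("landmarks must be finite")
    # no two points may coincide (degenerate TPS system)
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    np.fill_diagonal(d2, np.inf)
    if d2.min() <= 0.0:
        raise ConfigurationError("duplicate landmark coordinates")
    return pts


@dataclass
class BMDMap:
    """A masked areal-BMD raster (g/cm²) with its contour landmarks.

    ``values`` is NaN outside ``mask``; ``landmarks`` are mm coordinates in
    the raster's own frame.
    """

    values: np.ndarray
    mask: np.ndarray
    spacing: float = 0.5
    landmarks: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ConfigurationError("values and mask shapes differ")
        if self.spacing <= 0:
            raise ConfigurationError("spacing must be positive")
        if self.landmarks is not None:
            self.landmarks = as_landmarks(self.landmarks)

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def in_mask(self) -> np.ndarray:
        """Vector of values at in-mask pixels (row-major order)."""
        return self.values[self.mask]

    def copy(self) -> "BMDMap":
        return BMDMap(
            self.values.copy(),
            self.mask.copy(),
            self.spacing,
            None if self.landmarks is None else self.landmarks.copy(),
            dict(self.meta),
        )


@dataclass
class TemplateSpace:
    """The common analysis grid: mask, mean-shape landmarks and ROI masks.

    ``rois`` maps {"FN", "TR", "TOT"} to boolean rasters; FN and TR are
    disjoint and TOT is the full mask.
    """

    shape: tuple
    spacing: float
    mask: np.ndarray
    landmarks: np.ndarray
    rois: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if tuple(self.mask.shape) != tuple(self.shape):
            raise ConfigurationError("mask shape does not match template shape")
        self.landmarks = as_landmarks(self.landmarks)
        for name, roi in self.rois.items():
            roi = np.asarray(roi, dtype=bool)
            if roi.shape != self.mask.shape:
                raise ConfigurationError(f"ROI {name} shape mismatch")
            if np.any(roi & ~self.mask):
                raise ConfigurationError(f"ROI {name} leaves the template mask")
            self.rois[name] = roi

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    def pixel_coords_mm(self) -> np.ndarray:
        """(n_pixels, 2) array of (x, y) mm centres of in-mask pixels."""
        rr, cc = np.nonzero(self.mask)
        return np.column_stack([cc * self.spacing, rr * self.spacing])

    def roi_index(self, name: str) -> np.ndarray:
        """Boolean selector over the in-mask pixel vector for ROI ``name``."""
        if name not in self.rois:
            raise ConfigurationError(f"unknown ROI {name!r}")
        return self.rois[name][self.mask]

    def to_raster(self, vec: np.ndarray, fill=np.nan) -> np.ndarray:
        """Scatter an in-mask pixel vector back onto the full grid."""
        out = np.full(self.shape, fill, dtype=float)
        out[self.mask] = vec
        return out
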