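"""Thin-plate-spline landmark registration and template construction.

The warp uses the classic biharmonic kernel U(r) = r² log r² with an affine
part; with zero regularisation it interpolates the landmarks exactly while
minimising bending energy. Subject maps are resampled onto the template by
backward mapping (template pixel → subject coordinate) with bilinear
interpolation.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist

from .core import (
    BMDMap,
    ConfigurationError,
    RegistrationError,
    TemplateSpace,
    as_landmarks,
)

__all__ = ["TPSWarp", "fit_tps", "warp_to_template", "build_template"]


def _tps_kernel(r2: np.ndarray) -> np.ndarray:
    # U(r) = r^2 log r^2, continuously extended by 0 at r = 0
    with np.errstate(divide="ignore", invalid="ignore"):
        u = r2 * np.log(r2)
    return np.where(r2 > 0.0, u, 0.0)


@dataclass
class TPSWarp:
    """A fitted 2-D thin-plate-spline map f: R² → R²."""

    source: np.ndarray          # (n, 2) source landmarks, mm
    weights: np.ndarray         # (n, 2) kernel weights
    affine: np.ndarray          # (3, 2) rows: constant, x, y
    regularization: float = 0.0

    def transform(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        k = _tps_kernel(cdist(pts, self.source, "sqeuclidean"))
        p = np.column_stack([np.ones(len(pts)), pts])
        return k @ self.weights + p @ self.affine

    def side_condition_residual(self) -> float:
        """Max abs violation of Σw = 0 and Σw·x = Σw·y = 0."""
        p = np.column_stack([np.ones(len(self.source)), self.source])
        return float(np.abs(p.T @ self.weights).max())

    def bending_energy(self) -> float:
        k = _tps_kernel(cdist(self.source, self.source, "sqeuclidean"))
        return float(np.trace(self.weights.T @ k @ self.weights))

    def to_dict(self) -> dict:
        return {
            "source": self.source.tolist(),
            "weights": self.weights.tolist(),
            "affine": self.affine.tolist(),
            "regularization": self.regularization,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TPSWarp":
        return cls(
            np.asarray(d["source"], dtype=float),
            np.asarray(d["weights"], dtype=float),
            np.asarray(d["affine"], dtype=float),
            float(d.get("regularization", 0.0)),
        )


def fit_tps(source, target, regularization: float = 0.0) -> TPSWarp:
    """Fit the TPS warp carrying ``source`` landmarks onto ``target``.

    With ``regularization`` = 0 the warp interpolates every landmark
    exactly; larger values trade landmark fidelity for smoothness.
    """
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if src.shape != tgt.shape or src.ndim != 2 or src.shape[1] != 2:
        raise ConfigurationError("source/target landmark shapes must match (n, 2)")
    if regularization < 0:
        raise ConfigurationError("regularization must be >= 0")
    n = len(src)
    k = _tps_kernel(cdist(src, src, "sqeuclidean"))
    k[np.diag_indices(n)] += regularization
    p = np.column_stack([np.ones(n), src])
    lhs = np.zeros((n + 3, n + 3))
    lhs[:n, :n] = k
    lhs[:n, n:] = p
    lhs[n:, :n] = p.T
    rhs = np.zeros((n + 3, 2))
    rhs[:n] = tgt
    try:
        sol = np.linalg.solve(lhs, rhs)
    except np.linalg.LinAlgError as exc:  # collinear/duplicated landmarks
        raise RegistrationError(f"singular TPS system: {exc}") from exc
    if not np.all(np.isfinite(sol)):
        raise RegistrationError("non-finite TPS solution (degenerate landmarks)")
    return TPSWarp(src, sol[:n], sol[n:], regularization)


def _rim_fill(values: np.ndarray, mask: np.ndarray, rim: int) -> np.ndarray:
    """Extend in-mask values a few pixels outward by nearest-neighbour fill.

    Bilinear sampling at the mask boundary would otherwise mix NaN into
    every edge pixel and erode a one-pixel ring from the warped result.
    """
    if rim <= 0:
        return values
    _, (ir, ic) = ndimage.distance_transform_edt(~mask, return_indices=True)
    filled = values[ir, ic]
    keep = ndimage.binary_dilation(mask, iterations=rim)
    out = np.where(keep, filled, np.nan)
    out[mask] = values[mask]
    return out


def warp_to_template(
    bmd_map: BMDMap,
    template: TemplateSpace,
    warp: TPSWarp | None = None,
    min_coverage: float = 0.95,
    rim: int = 2,
) -> BMDMap:
    """Resample a subject map onto the template grid.

    Backward mapping: the warp is fitted from the template mean landmarks
    (source) to the subject landmarks (target); each template pixel centre
    is pushed through it and the subject raster is sampled bilinearly.
    Pixels landing outside the subject mask come back NaN; the fraction of
    valid template pixels is recorded as ``meta['coverage']`` with
    ``meta['low_coverage']`` set when it falls below ``min_coverage``.
    """
    if warp is None:
        if bmd_map.landmarks is None:
            raise ConfigurationError("map has no landmarks and no warp was given")
        warp = fit_tps(template.landmarks, bmd_map.landmarks)
    coords_mm = warp.transform(template.pixel_coords_mm())
    # mm -> fractional pixel indices in the subject raster
    cols = coords_mm[:, 0] / bmd_map.spacing
    rows = coords_mm[:, 1] / bmd_map.spacing
    source = _rim_fill(bmd_map.values, bmd_map.mask, rim)
    sampled = ndimage.map_coordinates(
        source, [rows, cols], order=1, mode="constant", cval=np.nan
    )
    values = np.full(template.shape, np.nan)
    values[template.mask] = sampled
    coverage = float(np.isfinite(sampled).mean()) if sampled.size else 0.0
    meta = dict(bmd_map.meta)
    meta["coverage"] = coverage
    meta["low_coverage"] = coverage < min_coverage
    return BMDMap(values, template.mask.copy(), template.spacing,
                  template.landmarks.copy(), meta)


def _fill_polygon(points_mm: np.ndarray, shape: tuple, spacing: float) -> np.ndarray:
    from skimage.draw import polygon

    rows = points_mm[:, 1] / spacing
    cols = points_mm[:, 0] / spacing
    rr, cc = polygon(rows, cols, shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def build_template(landmark_sets, masks, spacing: float = 0.5,
                   reference: TemplateSpace | None = None) -> TemplateSpace:
    """Average segmented shapes into a common template.

    Landmark sets are translated to the first subject's centroid before
    coordinate-wise averaging (so the template lives in an absolute frame
    anchored to subject 0); the template mask is the fill of the mean
    contour. ROI masks are transferred from ``reference`` (if given) by
    warping its FN/TR labels onto the mean shape; otherwise only TOT is
    populated.
    """
    sets = [as_landmarks(s) for s in landmark_sets]
    if len(sets) < 2:
        raise ConfigurationError("need at least two subjects to build a template")
    if len(masks) != len(sets):
        raise ConfigurationError("one mask per landmark set required")
    shape = np.asarray(masks[0]).shape
    anchor = sets[0].mean(axis=0)
    centred = np.stack([s - s.mean(axis=0) for s in sets])
    mean_lm = centred.mean(axis=0) + anchor
    mask = _fill_polygon(mean_lm, shape, spacing)

    rois = {"TOT": mask.copy()}
    if reference is not None:
        to_ref = fit_tps(mean_lm, reference.landmarks)
        coords_mm = to_ref.transform(
            np.column_stack(np.nonzero(mask))[:, ::-1] * spacing
        )
        rr = np.round(coords_mm[:, 1] / reference.spacing).astype(int)
        cc = np.round(coords_mm[:, 0] / reference.spacing).astype(int)
        inside = (
            (rr >= 0) & (rr < reference.shape[0])
            & (cc >= 0) & (cc < reference.shape[1])
        )
        for name in ("FN", "TR"):
            if name not in reference.rois:
                continue
            lab = np.zeros(mask.sum(), dtype=bool)
            lab[inside] = reference.rois[name][rr[inside], cc[inside]]
            roi = np.zeros(shape, dtype=bool)
            roi[mask] = lab
            rois[name] = roi
        if "FN" in rois and "TR" in rois:
            rois["TR"] &= ~rois["FN"]
    return TemplateSpace(shape, spacing, mask, mean_lm, rois,
                         meta={"n_subjects": len(sets)})
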