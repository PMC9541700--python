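"""Synthetic DXA-like cohorts with known ground truth.

The generator emulates the statistical structure the atlas and bone-age
estimator assume: a smooth spatially varying median BMD surface that
declines with age, subject-level bone-age offsets ("same path, different
speed"), a subject-level quantile offset, independent pixel noise,
repositioning noise for repeat scans, per-scanner linear calibration
effects, and fracture-type-specific deficit patterns (a focal band across
the femoral neck for FN fractures, a diffuse trochanteric deficit for TR
fractures). The femur silhouette is stylised: a head circle, a neck
capsule, a greater-trochanter bump and a shaft — only the topology (one
connected mask, 65 contour landmarks, three ROIs) matters downstream.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import ndimage

from .core import BMDMap, ConfigurationError, TemplateSpace

__all__ = [
    "FractureModel",
    "SimConfig",
    "GroundTruth",
    "ScanPair",
    "make_template_shape",
    "true_median_map",
    "simulate_subject",
    "simulate_cohort",
    "simulate_repeat_pair",
]

_MIN_MASK_PIXELS = 1000


@dataclass(frozen=True)
class FractureModel:
    """Fracture-risk and deficit-pattern parameters.

    Risk is logistic in the subject's bone-age excess (years older than
    chronological age); conditional on fracture, the type is FN with
    probability ``fn_fraction`` else TR. Deficits are subtracted from the
    subject surface: a Gaussian band across the femoral neck (FN) or a
    blurred trochanteric-ROI field (TR), both in g/cm².
    """

    prevalence: float = 0.02
    hazard_slope_per_year: float = 0.18
    fn_fraction: float = 0.7
    fn_amp: float = 0.03
    tr_amp: float = 0.02
    band_sigma_mm: float = 2.5
    tr_blur_mm: float = 2.0


@dataclass(frozen=True)
class SimConfig:
    grid_shape: tuple = (220, 160)
    pixel_spacing_mm: float = 0.5
    age_range: tuple = (20.0, 97.0)
    n_subjects: int = 500
    bone_age_offset_sd: float = 7.0       # years
    quantile_offset_sd: float = 1.0       # z units
    population_sd: float = 0.06           # g/cm² per unit z
    pixel_noise_sd: float = 0.02          # g/cm²
    repeat_noise_sd: float = 0.02         # g/cm²
    landmark_jitter_sd: float = 0.5       # mm per coordinate
    reposition_scale_sd: float = 0.01     # log-scale SD of similarity morph
    reposition_rot_sd: float = 0.01       # radians
    reposition_shift_sd: float = 0.5      # mm
    decline_per_decade: float = 0.05      # g/cm² per decade (at unit decline field)
    decline_onset_age: float = 45.0
    decline_softness: float = 4.0         # softplus width, years
    scanners: dict = field(default_factory=lambda: {"A": (1.0, 0.0)})
    scanner_probs: Optional[dict] = None
    fracture_model: FractureModel = field(default_factory=FractureModel)
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.age_range
        if not (20.0 <= lo < hi <= 97.0):
            raise ConfigurationError("age_range must lie within [20, 97]")
        for name in ("bone_age_offset_sd", "quantile_offset_sd", "population_sd",
                     "pixel_noise_sd", "repeat_noise_sd", "landmark_jitter_sd",
                     "reposition_scale_sd", "reposition_rot_sd",
                     "reposition_shift_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if len(self.grid_shape) != 2 or min(self.grid_shape) < 16:
            raise ConfigurationError("grid_shape must be a (rows, cols) pair")
        for slope, _ in self.scanners.values():
            if slope <= 0:
                raise ConfigurationError("scanner slopes must be positive")

    def noise_free(self) -> "SimConfig":
        """Copy with every stochastic nuisance switched off (tests/oracles)."""
        return replace(
            self, bone_age_offset_sd=0.0, quantile_offset_sd=0.0,
            pixel_noise_sd=0.0, repeat_noise_sd=0.0, landmark_jitter_sd=0.0,
            reposition_scale_sd=0.0, reposition_rot_sd=0.0,
            reposition_shift_sd=0.0,
        )


class _FemurGeometry:
    """Analytic stylised proximal-femur silhouette in mm coordinates."""

    def __init__(self, config: SimConfig):
        rows, cols = config.grid_shape
        s = config.pixel_spacing_mm
        self.W = cols * s
        self.H = rows * s
        w, h = self.W, self.H
        self.head_c = np.array([0.64 * w, 0.27 * h])
        self.head_r = 0.30 * w
        self.troch_c = np.array([0.30 * w, 0.50 * h])
        self.troch_r = 0.19 * w
        self.neck_hw = 0.15 * w
        self.shaft_x = (0.12 * w, 0.50 * w)
        self.shaft_y = (0.46 * h, 0.95 * h)
        axis = self.troch_c - self.head_c
        self.axis_len = float(np.hypot(*axis))
        self.axis_u = axis / self.axis_len

    def _neck_t_d(self, pts):
        """Along-axis coordinate t in [0,1] and perpendicular distance (mm)."""
        rel = pts - self.head_c
        t = rel @ self.axis_u / self.axis_len
        perp = rel - np.outer(t * self.axis_len, self.axis_u)
        return t, np.hypot(perp[:, 0], perp[:, 1])

    def indicator(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        head = np.hypot(*(pts - self.head_c).T) <= self.head_r
        troch = np.hypot(*(pts - self.troch_c).T) <= self.troch_r
        t, d = self._neck_t_d(pts)
        neck = (d <= self.neck_hw) & (t >= 0.0) & (t <= 1.0)
        shaft = (
            (pts[:, 0] >= self.shaft_x[0]) & (pts[:, 0] <= self.shaft_x[1])
            & (pts[:, 1] >= self.shaft_y[0]) & (pts[:, 1] <= self.shaft_y[1])
        )
        return head | troch | neck | shaft

    def fn_indicator(self, pts: np.ndarray) -> np.ndarray:
        """Femoral-neck ROI: the neck capsule outside the head core."""
        pts = np.atleast_2d(pts)
        t, d = self._neck_t_d(pts)
        in_neck = (d <= self.neck_hw) & (t >= 0.05) & (t <= 0.9)
        head_core = np.hypot(*(pts - self.head_c).T) <= 0.8 * self.head_r
        troch_core = np.hypot(*(pts - self.troch_c).T) <= 0.6 * self.troch_r
        return in_neck & ~head_core & ~troch_core

    def tr_indicator(self, pts: np.ndarray) -> np.ndarray:
        """Trochanteric ROI: trochanter bump plus upper shaft, minus FN."""
        pts = np.atleast_2d(pts)
        troch = np.hypot(*(pts - self.troch_c).T) <= self.troch_r
        upper_shaft = (
            (pts[:, 0] >= self.shaft_x[0]) & (pts[:, 0] <= self.shaft_x[1])
            & (pts[:, 1] >= self.shaft_y[0]) & (pts[:, 1] <= 0.64 * self.H)
        )
        return (troch | upper_shaft) & ~self.fn_indicator(pts)

    def band_profile(self, pts: np.ndarray, sigma_mm: float) -> np.ndarray:
        """Unit-amplitude band across the mid neck, confined to the FN ROI."""
        pts = np.atleast_2d(pts)
        t, _ = self._neck_t_d(pts)
        along_mm = (t - 0.45) * self.axis_len
        return np.exp(-0.5 * (along_mm / sigma_mm) ** 2) * self.fn_indicator(pts)


def _grid_coords_mm(shape, spacing):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    return np.column_stack([cc.ravel() * spacing, rr.ravel() * spacing])


def _contour_landmarks(mask: np.ndarray, spacing: float, n: int = 65) -> np.ndarray:
    from skimage import measure

    contours = measure.find_contours(mask.astype(float), 0.5)
    contour = max(contours, key=len)  # (row, col) closed polyline
    pts = contour[:, ::-1] * spacing  # -> (x, y) mm
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    # enforce clockwise orientation in image coords (y down)
    area = 0.5 * np.sum(pts[:, 0] * np.roll(pts[:, 1], -1)
                        - np.roll(pts[:, 0], -1) * pts[:, 1])
    if area < 0:
        pts = pts[::-1]
    # anchor: start at topmost point (ties: leftmost) for a stable ordering
    start = np.lexsort((pts[:, 0], pts[:, 1]))[0]
    pts = np.roll(pts, -start, axis=0)
    closed = np.vstack([pts, pts[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, arc[-1], n, endpoint=False)
    out = np.column_stack([
        np.interp(targets, arc, closed[:, 0]),
        np.interp(targets, arc, closed[:, 1]),
    ])
    return out


def make_template_shape(config: SimConfig) -> TemplateSpace:
    """Build the stylised femur template: mask, 65 landmarks, FN/TR/TOT ROIs."""
    geom = _FemurGeometry(config)
    shape = tuple(config.grid_shape)
    spacing = config.pixel_spacing_mm
    pts = _grid_coords_mm(shape, spacing)
    mask = geom.indicator(pts).reshape(shape)
    if mask.sum() < _MIN_MASK_PIXELS:
        raise ConfigurationError(
            f"template mask has {int(mask.sum())} pixels (< {_MIN_MASK_PIXELS}); "
            "enlarge grid_shape"
        )
    fn = geom.fn_indicator(pts).reshape(shape) & mask
    tr = geom.tr_indicator(pts).reshape(shape) & mask & ~fn
    landmarks = _contour_landmarks(mask, spacing)
    return TemplateSpace(
        shape, spacing, mask, landmarks,
        rois={"FN": fn, "TR": tr, "TOT": mask.copy()},
        meta={"synthetic": True},
    )


class GroundTruth:
    """The generator's own truth: median surface, deficits, subject draws.

    ``median_values(points, age)`` is the noise-free population median
    surface in closed form: base(p) − (rate/10)·softplus(age − onset)·d(p),
    with the spatial decline field d(p) strongest near the trochanter. Both
    components are exposed so tests can compute expectations analytically.
    """

    def __init__(self, config: SimConfig, template: TemplateSpace | None = None):
        self.config = config
        self.geometry = _FemurGeometry(config)
        self.template = template if template is not None else make_template_shape(config)
        self._deficit_rasters = self._build_deficit_rasters()
        # per-subject draws, filled by simulate_cohort
        self.ages: np.ndarray | None = None
        self.bone_age_offsets: np.ndarray | None = None
        self.quantile_offsets: np.ndarray | None = None
        self.scanner_ids: list | None = None
        self.fracture_labels: np.ndarray | None = None

    # ---- analytic surface -------------------------------------------------
    def base_field(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        w, h = self.geometry.W, self.geometry.H
        x, y = pts[:, 0], pts[:, 1]
        return (0.95
                + 0.15 * np.sin(2 * np.pi * x / (0.7 * w))
                * np.cos(2 * np.pi * y / (0.9 * h))
                + 0.10 * (1.0 - y / h))

    def decline_field(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        c = self.geometry.troch_c
        s = 0.19 * self.geometry.W
        r2 = np.sum((pts - c) ** 2, axis=1)
        return 0.7 + 0.6 * np.exp(-r2 / (2 * s * s))

    def age_decline(self, age) -> np.ndarray:
        """Softplus years-past-onset; strictly increasing in age."""
        cfg = self.config
        z = (np.asarray(age, dtype=float) - cfg.decline_onset_age) / cfg.decline_softness
        return cfg.decline_softness * np.log1p(np.exp(z))

    def median_values(self, pts: np.ndarray, age: float) -> np.ndarray:
        rate = self.config.decline_per_decade / 10.0
        return self.base_field(pts) - rate * self.age_decline(age) * self.decline_field(pts)

    def deficit_values(self, pts: np.ndarray, fracture: str) -> np.ndarray:
        """Sample the fracture deficit field (g/cm²) at mm points."""
        pts = np.atleast_2d(pts)
        if fracture == "none":
            return np.zeros(len(pts))
        if fracture not in self._deficit_rasters:
            raise ConfigurationError(f"unknown fracture label {fracture!r}")
        s = self.config.pixel_spacing_mm
        return ndimage.map_coordinates(
            self._deficit_rasters[fracture],
            [pts[:, 1] / s, pts[:, 0] / s], order=1, mode="nearest",
        )

    def _build_deficit_rasters(self) -> dict:
        fm = self.config.fracture_model
        tpl = self.template
        pts = _grid_coords_mm(tpl.shape, tpl.spacing)
        band = self.geometry.band_profile(pts, fm.band_sigma_mm).reshape(tpl.shape)
        tr = ndimage.gaussian_filter(
            tpl.rois["TR"].astype(float), fm.tr_blur_mm / tpl.spacing
        )
        return {"FN": fm.fn_amp * band, "TR": fm.tr_amp * tr}

    def band_mask(self, half_width_sigmas: float = 2.0) -> np.ndarray:
        """Template raster of the injected FN band support (tests/localisation)."""
        fm = self.config.fracture_model
        raster = self._deficit_rasters["FN"]
        return (raster >= fm.fn_amp * np.exp(-0.5 * half_width_sigmas ** 2)) \
            & self.template.mask


def true_median_map(gt: GroundTruth, age: float) -> BMDMap:
    """Evaluate the ground-truth median surface on the template grid."""
    lo, hi = gt.config.age_range
    if not (lo <= age <= hi):
        raise ValueError(f"age {age} outside configured range [{lo}, {hi}]")
    tpl = gt.template
    values = np.full(tpl.shape, np.nan)
    values[tpl.mask] = gt.median_values(tpl.pixel_coords_mm(), age)
    return BMDMap(values, tpl.mask.copy(), tpl.spacing, tpl.landmarks.copy(),
                  meta={"age_years": float(age), "truth": "median"})


def _similarity(rng, config):
    """Random small similarity transform (repositioning / morphology)."""
    scale = float(np.exp(rng.normal(0.0, config.reposition_scale_sd)))
    theta = float(rng.normal(0.0, config.reposition_rot_sd))
    shift = rng.normal(0.0, config.reposition_shift_sd, size=2)
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]])
    return scale, rot, shift


def simulate_subject(
    gt: GroundTruth,
    age: float,
    scanner: str = "A",
    seed=None,
    *,
    bone_age_offset: float | None = None,
    quantile_offset: float | None = None,
    fracture: str = "none",
    noise_sd: float | None = None,
    rng=None,
) -> BMDMap:
    """Simulate one DXA acquisition of one subject.

    The subject's surface is the population median evaluated at
    ``age + bone_age_offset``, shifted by ``quantile_offset`` (z units ×
    population SD) and minus any fracture deficit; the acquisition adds a
    small similarity repositioning of the bone, landmark jitter, iid pixel
    noise and the scanner's linear calibration. Offsets left as None are
    drawn from the configured SDs.
    """
    cfg = gt.config
    if scanner not in cfg.scanners:
        raise ConfigurationError(f"unknown scanner {scanner!r}")
    lo, hi = cfg.age_range
    if not (lo <= age <= hi):
        raise ValueError(f"age {age} outside configured range [{lo}, {hi}]")
    if rng is None:
        rng = np.random.default_rng(seed)
    if bone_age_offset is None:
        bone_age_offset = float(rng.normal(0.0, cfg.bone_age_offset_sd))
    if quantile_offset is None:
        quantile_offset = float(rng.normal(0.0, cfg.quantile_offset_sd))

    tpl = gt.template
    centre = tpl.landmarks.mean(axis=0)
    scale, rot, shift = _similarity(rng, cfg)
    grid = _grid_coords_mm(tpl.shape, tpl.spacing)
    if scale == 1.0 and np.all(shift == 0.0) and rot[0, 1] == 0.0:
        lm = tpl.landmarks.copy()            # exact identity acquisition
        back = grid
    else:
        lm = (tpl.landmarks - centre) @ rot.T * scale + centre + shift
        back = ((grid - centre - shift) / scale) @ rot + centre
    lm = lm + rng.normal(0.0, cfg.landmark_jitter_sd, size=lm.shape)
    inside = gt.geometry.indicator(back)
    pts = back[inside]

    surf = gt.median_values(pts, age + bone_age_offset)
    surf = surf + quantile_offset * cfg.population_sd
    surf = surf - gt.deficit_values(pts, fracture)
    sd = cfg.pixel_noise_sd if noise_sd is None else noise_sd
    if sd > 0:
        surf = surf + rng.normal(0.0, sd, size=surf.shape)
    slope, intercept = cfg.scanners[scanner]
    surf = slope * surf + intercept

    values = np.full(tpl.shape, np.nan)
    mask = inside.reshape(tpl.shape)
    values[mask] = surf
    return BMDMap(values, mask, tpl.spacing, lm, meta={
        "age_years": float(age), "scanner": scanner,
        "bone_age_offset": float(bone_age_offset),
        "quantile_offset": float(quantile_offset),
        "fracture_status": fracture,
    })


def _fracture_prob(offset, fm: FractureModel):
    if fm.prevalence <= 0:
        return 0.0
    base = np.log(fm.prevalence / (1.0 - fm.prevalence))
    return 1.0 / (1.0 + np.exp(-(base + fm.hazard_slope_per_year * offset)))


def simulate_cohort(config: SimConfig):
    """Simulate a full cohort.

    Returns ``(maps, cohort, gt)``: the list of subject BMDMaps, a cohort
    table (subject_id, age_years, scanner, bmi, fracture_status,
    followup_years) and the GroundTruth with per-subject draws attached.
    One seed sequence spawns a child per subject, so enlarging the cohort
    never reshuffles earlier subjects.
    """
    import pandas as pd

    gt = GroundTruth(config)
    n = config.n_subjects
    children = np.random.SeedSequence(config.seed).spawn(n)
    names = list(config.scanners)
    if config.scanner_probs is None:
        probs = np.full(len(names), 1.0 / len(names))
    else:
        probs = np.array([config.scanner_probs[k] for k in names], dtype=float)
        probs = probs / probs.sum()
    fm = config.fracture_model
    lo, hi = config.age_range

    maps, rows = [], []
    ages = np.empty(n)
    d_age = np.empty(n)
    z_off = np.empty(n)
    scanners = []
    labels = np.empty(n, dtype=object)
    for i in range(n):
        rng = np.random.default_rng(children[i])
        ages[i] = rng.uniform(lo, hi)
        d_age[i] = rng.normal(0.0, config.bone_age_offset_sd)
        z_off[i] = rng.normal(0.0, config.quantile_offset_sd)
        scanners.append(names[rng.choice(len(names), p=probs)])
        p = _fracture_prob(d_age[i], fm)
        if rng.uniform() < p:
            labels[i] = "FN" if rng.uniform() < fm.fn_fraction else "TR"
        else:
            labels[i] = "none"
        bmi = float(rng.normal(26.0, 4.0))
        m = simulate_subject(
            gt, float(ages[i]), scanners[i], rng=rng,
            bone_age_offset=float(d_age[i]), quantile_offset=float(z_off[i]),
            fracture=str(labels[i]),
        )
        m.meta["subject_id"] = f"S{i:05d}"
        maps.append(m)
        rows.append({
            "subject_id": f"S{i:05d}", "age_years": float(ages[i]),
            "scanner": scanners[i], "bmi": bmi,
            "fracture_status": str(labels[i]), "followup_years": 5.0,
        })
    gt.ages = ages
    gt.bone_age_offsets = d_age
    gt.quantile_offsets = z_off
    gt.scanner_ids = scanners
    gt.fracture_labels = labels
    return maps, pd.DataFrame(rows), gt


@dataclass
class ScanPair:
    """Two same-day acquisitions of one subject (repositioned between)."""

    first: BMDMap
    second: BMDMap
    subject: int


def simulate_repeat_pair(gt: GroundTruth, subject: int, seed=None) -> ScanPair:
    """Re-acquire a previously simulated subject twice.

    Both scans share the subject's underlying surface (age, offsets,
    fracture status, scanner); each gets fresh repositioning, landmark
    jitter and pixel noise at ``repeat_noise_sd``.
    """
    if gt.ages is None:
        raise ConfigurationError("simulate_cohort must run before repeat pairs")
    ss = np.random.SeedSequence(seed).spawn(2)
    scans = []
    for k in range(2):
        scans.append(simulate_subject(
            gt, float(gt.ages[subject]), gt.scanner_ids[subject],
            rng=np.random.default_rng(ss[k]),
            bone_age_offset=float(gt.bone_age_offsets[subject]),
            quantile_offset=float(gt.quantile_offsets[subject]),
            fracture=str(gt.fracture_labels[subject]),
            noise_sd=gt.config.repeat_noise_sd,
        ))
    return ScanPair(scans[0], scans[1], subject)
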