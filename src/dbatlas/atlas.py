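"""Per-pixel age-conditional BMD quantile atlas.

The conditional distribution of BMD at each template pixel is estimated as
a function of age by Gaussian-kernel local weighting: at each age-grid
point, subjects receive weights exp(-((age_i - a) / h)² / 2) and weighted
empirical quantiles are read off at 99 equispaced levels, followed by a
monotone rearrangement across levels. The 0.5-level slice is the median
aging trajectory used for bone-age estimation; inverting the quantile
function gives the conditional CDF used for quantile maps.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import BMDMap, ConfigurationError, TemplateSpace

__all__ = [
    "PixelQuantileAtlas",
    "CalibrationField",
    "ReferenceModel",
    "ROISummary",
    "fit_atlas",
    "fit_quantiles",
    "monotone_rearrange",
    "median_map",
    "pixel_cdf",
    "fit_quantile_match_calibration",
    "build_reference",
    "roi_summary",
]

DEFAULT_LEVELS = np.linspace(0.01, 0.99, 99)
DEFAULT_AGE_GRID = np.arange(20.0, 97.0 + 1e-9, 0.25)
CDF_CLAMP = (0.005, 0.995)


def monotone_rearrange(q: np.ndarray, axis: int = -1) -> np.ndarray:
    """Enforce nondecreasing quantiles across levels (rearrangement)."""
    return np.maximum.accumulate(q, axis=axis)


def _weighted_quantiles(vs, pos, nvalid, levels):
    """Interpolate weighted empirical quantiles for every pixel column.

    ``vs``: (n, P) values sorted ascending per column (NaN last);
    ``pos``: (n, P) weighted plotting positions (cum - w/2)/W, nondecreasing;
    ``nvalid``: (P,) count of finite entries. Returns (L, P).
    """
    n, n_pix = vs.shape
    lv = np.asarray(levels, dtype=float)[:, None]
    n_lev = lv.shape[0]
    # vectorised binary search: idx = count of positions strictly below u
    lo = np.zeros((n_lev, n_pix), dtype=np.int64)
    hi = np.broadcast_to(nvalid[None, :], (n_lev, n_pix)).copy()
    for _ in range(int(np.ceil(np.log2(n + 1))) + 2):
        mid = (lo + hi) // 2
        pmid = np.take_along_axis(pos, np.minimum(mid, n - 1), axis=0)
        right = (pmid < lv) & (mid < hi)
        lo = np.where(right, mid + 1, lo)
        hi = np.where(right, hi, mid)
    idx = lo
    last = np.maximum(nvalid - 1, 0)[None, :]
    i1 = np.minimum(idx, last)
    i0 = np.maximum(i1 - 1, 0)
    v0 = np.take_along_axis(vs, i0, axis=0)
    v1 = np.take_along_axis(vs, i1, axis=0)
    p0 = np.take_along_axis(pos, i0, axis=0)
    p1 = np.take_along_axis(pos, i1, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.clip((lv - p0) / (p1 - p0), 0.0, 1.0)
    t = np.where(p1 > p0, t, 0.0)
    out = v0 + t * (v1 - v0)
    # above the top position -> top order statistic; empty pixel -> NaN
    top = np.take_along_axis(vs, last, axis=0)
    out = np.where(idx > last, top, out)
    out = np.where(nvalid[None, :] == 0, np.nan, out)
    return out


def fit_quantiles(values, ages, age_grid=None, levels=None, bandwidth=5.0):
    """Kernel-weighted conditional quantiles of a (subjects × pixels) matrix.

    Returns ``(Q, n_effective)`` with Q of shape (pixels, ages, levels),
    monotone in the level axis. NaN entries (uncovered pixels) are ignored
    with per-pixel renormalised weights.
    """
    v = np.asarray(values, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if v.ndim != 2 or len(ages) != v.shape[0]:
        raise ConfigurationError("values must be (n_subjects, n_pixels)")
    if bandwidth <= 0:
        raise ConfigurationError("bandwidth must be positive")
    age_grid = DEFAULT_AGE_GRID if age_grid is None else np.asarray(age_grid, float)
    levels = DEFAULT_LEVELS if levels is None else np.asarray(levels, float)
    if np.any(np.diff(age_grid) <= 0) or np.any(np.diff(levels) <= 0):
        raise ConfigurationError("age_grid and levels must be strictly increasing")

    order = np.argsort(v, axis=0, kind="stable")  # NaNs sort last
    vs = np.take_along_axis(v, order, axis=0)
    valid = np.isfinite(vs)
    nvalid = valid.sum(axis=0)

    n_pix = v.shape[1]
    q = np.empty((n_pix, len(age_grid), len(levels)), dtype=np.float32)
    neff = np.empty(len(age_grid))
    for j, a in enumerate(age_grid):
        w = np.exp(-0.5 * ((ages - a) / bandwidth) ** 2)
        neff[j] = float(w.sum())
        wcol = w[order] * valid
        cw = np.cumsum(wcol, axis=0)
        tot = cw[-1]
        with np.errstate(invalid="ignore", divide="ignore"):
            pos = (cw - 0.5 * wcol) / tot
        q[:, j, :] = _weighted_quantiles(vs, pos, nvalid, levels).T
    q = monotone_rearrange(q, axis=2)
    return q, neff


@dataclass
class PixelQuantileAtlas:
    """Smooth per-pixel quantile surfaces Q(pixel, age, level) over age."""

    Q: np.ndarray                  # (n_pixels, n_ages, n_levels), float32
    age_grid: np.ndarray
    levels: np.ndarray
    template: TemplateSpace
    bandwidth: float
    n_effective: np.ndarray
    meta: dict = field(default_factory=dict)

    MIN_EFFECTIVE = 10.0

    def __post_init__(self):
        self.age_grid = np.asarray(self.age_grid, dtype=float)
        self.levels = np.asarray(self.levels, dtype=float)
        if self.Q.shape != (self.template.n_pixels, len(self.age_grid),
                            len(self.levels)):
            raise ConfigurationError("atlas Q shape inconsistent")

    @property
    def reliable(self) -> np.ndarray:
        """Age-grid points with adequate effective sample size."""
        return self.n_effective >= self.MIN_EFFECTIVE

    @property
    def age_span(self) -> tuple:
        return float(self.age_grid[0]), float(self.age_grid[-1])

    def _age_bracket(self, age: float):
        lo, hi = self.age_span
        if not (lo <= age <= hi):
            raise ValueError(f"age {age} outside atlas span [{lo}, {hi}]")
        j = int(np.clip(np.searchsorted(self.age_grid, age, side="right") - 1,
                        0, len(self.age_grid) - 2))
        f = (age - self.age_grid[j]) / (self.age_grid[j + 1] - self.age_grid[j])
        return j, float(np.clip(f, 0.0, 1.0))

    def quantile_values(self, age: float, level: float = 0.5) -> np.ndarray:
        """In-mask vector of the level-quantile surface at an age (interp)."""
        li = np.searchsorted(self.levels, level)
        if li >= len(self.levels) or not np.isclose(self.levels[li], level):
            raise ConfigurationError(f"level {level} not on the stored grid")
        j, f = self._age_bracket(age)
        sl = self.Q[:, j, li].astype(float)
        if f > 0:
            sl = (1.0 - f) * sl + f * self.Q[:, j + 1, li].astype(float)
        return sl

    def median_values(self, age: float) -> np.ndarray:
        return self.quantile_values(age, 0.5)

    def median_map(self, age: float) -> BMDMap:
        tpl = self.template
        values = tpl.to_raster(self.median_values(age))
        return BMDMap(values, tpl.mask.copy(), tpl.spacing,
                      tpl.landmarks.copy(), meta={"age_years": float(age)})

    def median_stack(self, ages: np.ndarray) -> np.ndarray:
        """(n_ages, n_pixels) median maps at arbitrary ages (vectorised)."""
        ages = np.asarray(ages, dtype=float)
        lo, hi = self.age_span
        if ages.min() < lo or ages.max() > hi:
            raise ValueError("requested ages outside atlas span")
        li = int(np.searchsorted(self.levels, 0.5))
        qm = self.Q[:, :, li].astype(float)  # (P, A)
        j = np.clip(np.searchsorted(self.age_grid, ages, side="right") - 1,
                    0, len(self.age_grid) - 2)
        f = (ages - self.age_grid[j]) / (self.age_grid[j + 1] - self.age_grid[j])
        f = np.clip(f, 0.0, 1.0)
        return (qm[:, j] * (1.0 - f) + qm[:, j + 1] * f).T

    def cdf_values(self, values: np.ndarray, age: float) -> np.ndarray:
        """Per-pixel conditional CDF of an in-mask value vector at an age.

        Inverts the monotone quantile function by linear interpolation and
        clamps to [0.005, 0.995].
        """
        v = np.asarray(values, dtype=float)
        j, f = self._age_bracket(age)
        qa = self.Q[:, j, :].astype(float)
        if f > 0:
            qa = (1.0 - f) * qa + f * self.Q[:, j + 1, :].astype(float)
        idx = np.sum(qa < v[:, None], axis=1)  # count of levels below value
        n_lev = len(self.levels)
        i1 = np.clip(idx, 0, n_lev - 1)
        i0 = np.clip(idx - 1, 0, n_lev - 1)
        q0 = np.take_along_axis(qa, i0[:, None], axis=1)[:, 0]
        q1 = np.take_along_axis(qa, i1[:, None], axis=1)[:, 0]
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.clip((v - q0) / (q1 - q0), 0.0, 1.0)
        t = np.where(q1 > q0, t, 0.0)
        u = self.levels[i0] + t * (self.levels[i1] - self.levels[i0])
        u = np.where(v < qa[:, 0], CDF_CLAMP[0], u)
        u = np.where(v > qa[:, -1], CDF_CLAMP[1], u)
        u = np.where(np.isnan(v), np.nan, u)
        return np.clip(u, CDF_CLAMP[0], CDF_CLAMP[1])

    # ---- serialisation ---------------------------------------------------
    def save(self, path):
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("Q", data=self.Q, compression="gzip")
            f["age_grid"] = self.age_grid
            f["levels"] = self.levels
            f["n_effective"] = self.n_effective
            f["mask"] = self.template.mask.astype(np.uint8)
            f["landmarks"] = self.template.landmarks
            for name, roi in self.template.rois.items():
                f[f"roi/{name}"] = roi.astype(np.uint8)
            f.attrs["bandwidth"] = self.bandwidth
            f.attrs["spacing"] = self.template.spacing

    @classmethod
    def load(cls, path) -> "PixelQuantileAtlas":
        import h5py

        with h5py.File(path, "r") as f:
            mask = f["mask"][...].astype(bool)
            rois = {k: f[f"roi/{k}"][...].astype(bool) for k in f["roi"]}
            tpl = TemplateSpace(mask.shape, float(f.attrs["spacing"]), mask,
                                f["landmarks"][...], rois)
            return cls(f["Q"][...], f["age_grid"][...], f["levels"][...], tpl,
                       float(f.attrs["bandwidth"]), f["n_effective"][...])


def _stack_maps(maps: Sequence[BMDMap], template: TemplateSpace) -> np.ndarray:
    rows = []
    for m in maps:
        if m.shape != tuple(template.shape):
            raise ConfigurationError("map not in template space")
        rows.append(m.values[template.mask])
    return np.asarray(rows)


def fit_atlas(
    warped_maps: Sequence[BMDMap],
    ages,
    template: TemplateSpace,
    bandwidth: float = 5.0,
    age_grid=None,
    levels=None,
) -> PixelQuantileAtlas:
    """Fit the pixel quantile atlas from template-space maps."""
    ages = np.asarray(ages, dtype=float)
    if len(warped_maps) != len(ages):
        raise ConfigurationError("one age per map required")
    values = _stack_maps(warped_maps, template)
    q, neff = fit_quantiles(values, ages, age_grid=age_grid, levels=levels,
                            bandwidth=bandwidth)
    age_grid = DEFAULT_AGE_GRID if age_grid is None else np.asarray(age_grid, float)
    levels = DEFAULT_LEVELS if levels is None else np.asarray(levels, float)
    return PixelQuantileAtlas(q, age_grid, levels, template, float(bandwidth),
                              neff, meta={"n_subjects": len(warped_maps)})


def median_map(atlas: PixelQuantileAtlas, age: float) -> BMDMap:
    """The median aging trajectory M(age) as a template-space map."""
    return atlas.median_map(age)


def pixel_cdf(atlas: PixelQuantileAtlas, pixel: int, age: float, value: float) -> float:
    """Conditional P(BMD < value) at one in-mask pixel and age."""
    v = np.full(atlas.template.n_pixels, np.nan)
    v[pixel] = value
    return float(atlas.cdf_values(v, age)[pixel])


# ---- cross-scanner quantile-matching calibration --------------------------

@dataclass
class CalibrationField:
    """Per-pixel linear map making scanner B's BMD distribution match A's."""

    slope: np.ndarray         # (n_pixels,)
    intercept: np.ndarray
    flagged: np.ndarray       # pixels that fell back to the identity
    max_residual: float
    levels: np.ndarray

    def apply(self, values: np.ndarray) -> np.ndarray:
        return self.slope * values + self.intercept

    def apply_map(self, m: BMDMap, template: TemplateSpace) -> BMDMap:
        out = m.copy()
        out.values[template.mask] = self.apply(out.values[template.mask])
        return out


def fit_quantile_match_calibration(values_a, values_b, levels=None) -> CalibrationField:
    """Quantile-matching regression of scanner A on scanner B, per pixel.

    For each pixel, OLS of A's empirical quantiles on B's over levels
    0.05–0.95 (step 0.05); applying (slope, intercept) to B matches its
    per-pixel distribution to A's. Groups should be matched for age and BMI
    so the quantile differences reflect the scanners, not the cohorts.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ConfigurationError("values must be (n_subjects, n_pixels) per group")
    levels = np.arange(0.05, 0.9501, 0.05) if levels is None else np.asarray(levels)
    qa = np.nanquantile(a, levels, axis=0)
    qb = np.nanquantile(b, levels, axis=0)
    qbc = qb - qb.mean(axis=0)
    var_b = np.sum(qbc ** 2, axis=0)
    flagged = var_b <= 1e-16
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = np.sum(qbc * (qa - qa.mean(axis=0)), axis=0) / var_b
    slope = np.where(flagged, 1.0, slope)
    intercept = qa.mean(axis=0) - slope * qb.mean(axis=0)
    intercept = np.where(flagged, 0.0, intercept)
    resid = qa - (slope * qb + intercept)
    max_residual = float(np.nanmax(np.abs(resid))) if resid.size else 0.0
    return CalibrationField(slope, intercept, flagged, max_residual, levels)


# ---- ROI summaries: aBMD, T-score, Z-score --------------------------------

@dataclass
class ROISummary:
    roi: str
    abmd: float            # g/cm²
    t_score: float
    z_score: float


@dataclass
class ReferenceModel:
    """Young-adult and age-conditional reference for ROI aBMD scores.

    T-scores use the mean/SD of the young reference group (default ages
    20–39); Z-scores use kernel-smoothed age-conditional mean/SD curves.
    """

    age_grid: np.ndarray
    young_mean: dict
    young_sd: dict
    mean_curves: dict      # roi -> (n_ages,) array
    sd_curves: dict
    young_range: tuple = (20.0, 39.0)

    def age_mean(self, roi: str, age: float) -> float:
        return float(np.interp(age, self.age_grid, self.mean_curves[roi]))

    def age_sd(self, roi: str, age: float) -> float:
        return float(np.interp(age, self.age_grid, self.sd_curves[roi]))


def roi_abmd(m: BMDMap, template: TemplateSpace) -> dict:
    """Mean in-mask BMD over each ROI (NaN pixels excluded)."""
    vec = m.values[template.mask]
    out = {}
    for name in ("FN", "TR", "TOT"):
        if name not in template.rois:
            continue
        sel = template.roi_index(name)
        if not sel.any():
            raise ConfigurationError(f"ROI {name} is empty")
        out[name] = float(np.nanmean(vec[sel]))
    return out


def build_reference(
    maps: Sequence[BMDMap],
    ages,
    template: TemplateSpace,
    young_range=(20.0, 39.0),
    bandwidth: float = 5.0,
    age_grid=None,
) -> ReferenceModel:
    """Build young-adult and age-conditional ROI references from a cohort."""
    ages = np.asarray(ages, dtype=float)
    age_grid = (np.arange(20.0, 97.0 + 1e-9, 1.0) if age_grid is None
                else np.asarray(age_grid, float))
    table = {name: [] for name in template.rois if name in ("FN", "TR", "TOT")}
    for m in maps:
        vals = roi_abmd(m, template)
        for name in table:
            table[name].append(vals[name])
    young = (ages >= young_range[0]) & (ages <= young_range[1])
    if young.sum() < 2:
        raise ConfigurationError("need >= 2 subjects in the young reference range")
    young_mean, young_sd, mean_curves, sd_curves = {}, {}, {}, {}
    for name, vals in table.items():
        x = np.asarray(vals)
        young_mean[name] = float(x[young].mean())
        young_sd[name] = float(x[young].std(ddof=1))
        w = np.exp(-0.5 * ((ages[None, :] - age_grid[:, None]) / bandwidth) ** 2)
        tot = w.sum(axis=1)
        mu = (w @ x) / tot
        var = (w @ x ** 2) / tot - mu ** 2
        mean_curves[name] = mu
        sd_curves[name] = np.sqrt(np.maximum(var, 0.0))
    return ReferenceModel(age_grid, young_mean, young_sd, mean_curves,
                          sd_curves, tuple(young_range))


def roi_summary(
    m: BMDMap,
    template: TemplateSpace,
    reference: ReferenceModel,
    age: Optional[float] = None,
) -> dict:
    """aBMD with T- and Z-scores for every ROI of one template-space map."""
    if age is None:
        age = m.meta.get("age_years")
        if age is None:
            raise ConfigurationError("subject age required for Z-scores")
    out = {}
    for name, abmd in roi_abmd(m, template).items():
        t = (abmd - reference.young_mean[name]) / reference.young_sd[name]
        sd = reference.age_sd(name, age)
        z = (abmd - reference.age_mean(name, age)) / sd if sd > 0 else np.nan
        out[name] = ROISummary(name, abmd, float(t), float(z))
    return out
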