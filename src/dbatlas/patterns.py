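"""Fracture-pattern localisation on bone-age-normalised quantile maps.

Quantile maps cancel the aging component of BMD texture: each pixel of a
subject's map is replaced by the probability of observing a lower BMD at
that pixel among the population with a similar bone age (the atlas
conditional CDF evaluated at the subject's DBA). Group differences are
then tested pixel-by-pixel with a two-sided Mann–Whitney U test and
reported as Benjamini–Hochberg q-values — the minimum FDR level at which
each pixel would be declared significant.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .atlas import PixelQuantileAtlas
from .core import BMDMap, ConfigurationError

__all__ = [
    "QuantileMap",
    "PixelStatMap",
    "quantile_map",
    "mann_whitney_map",
    "fdr_qvalues",
    "pp_plot_data",
    "compare_groups",
]

Q_SIGNIFICANT = 0.05


@dataclass
class QuantileMap:
    """A bone-age-normalised map: per-pixel probabilities in [0.005, 0.995]."""

    values: np.ndarray          # in-mask vector
    dba_used: float

    def __post_init__(self):
        v = self.values[np.isfinite(self.values)]
        if v.size and (v.min() < 0.005 - 1e-12 or v.max() > 0.995 + 1e-12):
            raise ConfigurationError("quantile values outside the clamped range")


def quantile_map(m: BMDMap, dba: float, atlas: PixelQuantileAtlas) -> QuantileMap:
    """Normalise a template-space BMD map by the subject's bone age."""
    if m.shape != tuple(atlas.template.shape):
        raise ConfigurationError("map is not in template space")
    v = m.values[atlas.template.mask]
    return QuantileMap(atlas.cdf_values(v, dba), float(dba))


def _stack_quantiles(group) -> np.ndarray:
    rows = [g.values if isinstance(g, QuantileMap) else np.asarray(g, float)
            for g in group]
    return np.asarray(rows)


def mann_whitney_map(group_a, group_b, method: str = "asymptotic"):
    """Pixel-wise two-sided Mann–Whitney U between two groups of quantile maps.

    Returns ``(effect, p)`` in-mask vectors: effect is mean(A) − mean(B) of
    the quantile values, p the two-sided U-test p-value (normal
    approximation with tie and continuity correction by default; pass
    ``method='exact'`` for small-sample exact enumeration). Pixels constant
    across both groups get p = 1.
    """
    a = _stack_quantiles(group_a)
    b = _stack_quantiles(group_b)
    if len(a) < 2 or len(b) < 2:
        raise ConfigurationError("both groups need >= 2 subjects")
    effect = np.nanmean(a, axis=0) - np.nanmean(b, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.mannwhitneyu(a, b, axis=0, alternative="two-sided",
                                 method=method, use_continuity=True,
                                 nan_policy="omit")
    p = np.asarray(res.pvalue, dtype=float)
    p = np.where(np.isfinite(p), p, 1.0)  # zero-variance (all-tie) pixels
    return effect, np.clip(p, 0.0, 1.0)


def fdr_qvalues(p: np.ndarray, alpha: float = Q_SIGNIFICANT):
    """Benjamini–Hochberg q-values with the step-up monotonicity enforcement.

    The q-value of a pixel is the minimum FDR level at which it would be
    selected; ``significant`` marks q < ``alpha``.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ConfigurationError("p-values must lie in [0, 1]")
    flat = p.ravel()
    _, q, _, _ = multipletests(flat, alpha=alpha, method="fdr_bh")
    q = q.reshape(p.shape)
    return q, q < alpha


def pp_plot_data(p: np.ndarray):
    """Sorted p-values against uniform quantiles (k/m, p₍ₖ₎).

    Under a global null the curve tracks the identity; an excess of small
    p-values pulls it below the diagonal at small k/m.
    """
    p = np.sort(np.asarray(p, dtype=float).ravel())
    if p.size == 0:
        raise ConfigurationError("need at least one p-value")
    m = p.size
    return np.arange(1, m + 1) / m, p


@dataclass
class PixelStatMap:
    """Per-pixel group-comparison results on the template in-mask vector."""

    effect: np.ndarray
    p: np.ndarray
    q: np.ndarray
    significant: np.ndarray
    meta: dict = field(default_factory=dict)


def compare_groups(group_a, group_b, method: str = "asymptotic",
                   alpha: float = Q_SIGNIFICANT) -> PixelStatMap:
    """Mann–Whitney map plus FDR control in one call."""
    effect, p = mann_whitney_map(group_a, group_b, method=method)
    q, sig = fdr_qvalues(p, alpha=alpha)
    return PixelStatMap(effect, p, q, sig,
                        meta={"n_a": len(group_a), "n_b": len(group_b),
                              "alpha": alpha, "method": method})
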