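"""Fracture-risk classifier evaluation: ROC, PRC, bootstrap CIs, agreement.

All scores are evaluated in the "higher = higher risk" orientation; BMD
scores must be negated by the caller (``orient_bmd``) before comparison
with bone-age scores. ROC AUC is the trapezoidal area, equal under ties to
the Mann–Whitney U statistic divided by n₁·n₀; PRC AUC uses step-wise
(achievable) interpolation so low-prevalence results are not optimistic.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_curve,
)

from .core import ConfigurationError

__all__ = [
    "CurveResult",
    "roc",
    "prc",
    "bootstrap_auc",
    "dba_tscore_confusion",
    "correlations",
    "orient_bmd",
    "FRACTURE_LABELS",
]

FRACTURE_LABELS = ("none", "FN", "TR", "unspecified")


def orient_bmd(values) -> np.ndarray:
    """Negate a BMD-like score so that higher means higher risk."""
    return -np.asarray(values, dtype=float)


def _check_classes(labels) -> np.ndarray:
    y = np.asarray(labels).astype(bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present for curve analysis")
    return y


@dataclass
class CurveResult:
    kind: str                  # "roc" or "prc"
    x: np.ndarray              # FPR or recall
    y: np.ndarray              # TPR or precision
    thresholds: np.ndarray
    auc: float
    baseline: float            # 0.5 for ROC, prevalence for PRC
    ci95: tuple | None = None
    n_boot: int = 0
    meta: dict = field(default_factory=dict)


def roc(scores, labels) -> CurveResult:
    """ROC curve and trapezoidal AUC (higher score = case orientation)."""
    y = _check_classes(labels)
    s = np.asarray(scores, dtype=float)
    fpr, tpr, thr = roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return CurveResult("roc", fpr, tpr, thr, auc, baseline=0.5,
                       meta={"n_cases": int(y.sum()), "n_controls": int((~y).sum())})


def prc(scores, labels) -> CurveResult:
    """Precision–recall curve; AUC by step-wise (achievable) interpolation.

    The random-classifier baseline equals the case prevalence, which is
    attached to the result.
    """
    y = _check_classes(labels)
    s = np.asarray(scores, dtype=float)
    prec, rec, thr = precision_recall_curve(y, s)
    auc = float(average_precision_score(y, s))
    prevalence = float(y.mean())
    return CurveResult("prc", rec, prec, thr, auc, baseline=prevalence,
                       meta={"n_cases": int(y.sum()), "n_controls": int((~y).sum())})


def _auc_of(kind: str, scores, y) -> float:
    if kind == "roc":
        fpr, tpr, _ = roc_curve(y, scores, drop_intermediate=True)
        return float(np.trapezoid(tpr, fpr))
    return float(average_precision_score(y, scores))


def bootstrap_auc(
    scores,
    labels,
    n_boot: int = 1000,
    seed=None,
    kind: str = "roc",
    scores_b=None,
):
    """Stratified bootstrap percentile CI for an AUC (and a paired delta).

    Cases and controls are resampled separately: at ~2% prevalence an
    unstratified resample frequently contains no cases at all. When
    ``scores_b`` is given, the identical resamples are applied to both
    score columns and the CI of AUC_a − AUC_b is returned as well.
    """
    y = _check_classes(labels)
    s = np.asarray(scores, dtype=float)
    sb = None if scores_b is None else np.asarray(scores_b, dtype=float)
    rng = np.random.default_rng(seed)
    cases = np.flatnonzero(y)
    ctrls = np.flatnonzero(~y)
    aucs = np.empty(n_boot)
    deltas = np.empty(n_boot) if sb is not None else None
    for b in range(n_boot):
        idx = np.concatenate([
            rng.choice(cases, size=len(cases), replace=True),
            rng.choice(ctrls, size=len(ctrls), replace=True),
        ])
        yb = y[idx]
        aucs[b] = _auc_of(kind, s[idx], yb)
        if deltas is not None:
            deltas[b] = aucs[b] - _auc_of(kind, sb[idx], yb)
    out = {
        "auc": _auc_of(kind, s, y),
        "ci95": (float(np.percentile(aucs, 2.5)), float(np.percentile(aucs, 97.5))),
        "n_boot": int(n_boot),
        "stratified": True,
    }
    if deltas is not None:
        out["delta_auc"] = _auc_of(kind, s, y) - _auc_of(kind, sb, y)
        out["delta_ci95"] = (float(np.percentile(deltas, 2.5)),
                             float(np.percentile(deltas, 97.5)))
    return out


def dba_tscore_confusion(dba, t_scores, dba_cuts=None, t_cuts=(-2.5, -1.0)):
    """3×3 agreement matrix of DBA vs T-score diagnostic categories.

    T-score categories: osteoporotic (T ≤ −2.5), osteopenic, normal
    (T ≥ −1). When ``dba_cuts`` is None the DBA thresholds are obtained by
    inverting the cohort's fitted linear DBA~T relation at the two T cuts,
    so that an old bone age plays the role of a low T-score.
    Returns ``(matrix, agreement, dba_cuts)`` with rows = DBA category and
    columns = T category ordered (osteoporotic, osteopenic, normal).
    """
    d = np.asarray(dba, dtype=float)
    t = np.asarray(t_scores, dtype=float)
    if d.shape != t.shape or d.ndim != 1:
        raise ConfigurationError("dba and t_scores must be matching vectors")
    if np.ptp(t) == 0:
        raise ValueError("zero T-score variance: cannot fit DBA~T relation")
    if dba_cuts is None:
        slope, intercept = np.polyfit(t, d, 1)
        dba_cuts = tuple(slope * np.asarray(t_cuts) + intercept)
    cut_osteo, cut_normal = dba_cuts  # DBA at T=-2.5 (old) and T=-1 (younger)
    # category 0 = osteoporotic, 1 = osteopenic, 2 = normal
    t_cat = np.where(t <= t_cuts[0], 0, np.where(t < t_cuts[1], 1, 2))
    d_cat = np.where(d >= cut_osteo, 0, np.where(d > cut_normal, 1, 2))
    matrix = np.zeros((3, 3), dtype=int)
    for i, j in zip(d_cat, t_cat):
        matrix[i, j] += 1
    agreement = float(np.trace(matrix)) / len(d)
    return matrix, agreement, tuple(float(c) for c in dba_cuts)


def correlations(dba, age, t_scores=None, z_scores=None, n_age_bins: int = 12):
    """Pearson correlations of DBA with age and the conventional scores.

    Also summarises the median-DBA-versus-age relation: ages are split into
    equal-count bins, the median DBA per bin is regressed on the bin-mean
    age, and the slope/intercept are reported (an identity-like relation
    has slope ≈ 1).
    """
    d = np.asarray(dba, dtype=float)
    a = np.asarray(age, dtype=float)
    if len(d) < 3:
        raise ConfigurationError("need at least 3 subjects")

    def _r(x, y):
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise ValueError("zero variance: correlation undefined")
        r, p = stats.pearsonr(x, y)
        return {"r": float(r), "p": float(p)}

    out = {"dba_age": _r(a, d)}
    if t_scores is not None:
        out["dba_tscore"] = _r(np.asarray(t_scores, float), d)
    if z_scores is not None:
        out["dba_zscore"] = _r(np.asarray(z_scores, float), d)

    edges = np.quantile(a, np.linspace(0, 1, n_age_bins + 1))
    which = np.clip(np.searchsorted(edges, a, side="right") - 1, 0, n_age_bins - 1)
    xs, ys = [], []
    for b in range(n_age_bins):
        sel = which == b
        if sel.sum() >= 3:
            xs.append(a[sel].mean())
            ys.append(np.median(d[sel]))
    slope, intercept = np.polyfit(xs, ys, 1)
    out["median_dba_vs_age"] = {"slope": float(slope), "intercept": float(intercept)}
    return out
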