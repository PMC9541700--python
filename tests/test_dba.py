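"""Bone-age estimation: RMSE curve, argmin contracts, precision."""
import numpy as np
import pytest

from dbatlas import dba as D
from dbatlas.core import BMDMap, CoverageError


def test_rmse_zero_at_own_age(tiny_setup):
    atl = tiny_setup["atlas"]
    m = atl.median_map(70.0)
    ages, rmse, used = D.rmse_curve(m, atl, age_step=0.5)
    assert rmse[np.searchsorted(ages, 70.0)] == 0.0
    assert used == atl.template.n_pixels
    assert np.all(rmse >= 0)


def test_rmse_constant_offset_closed_form(tiny_setup):
    atl = tiny_setup["atlas"]
    m = atl.median_map(70.0)
    m.values = m.values + 0.04
    ages, rmse, _ = D.rmse_curve(m, atl, age_step=0.5)
    assert rmse[np.searchsorted(ages, 70.0)] == pytest.approx(0.04, rel=1e-9)


def test_rmse_matches_naive_loop(tiny_setup):
    # independent oracle: recompute the curve pixel-by-pixel per age
    atl = tiny_setup["atlas"]
    rng = np.random.default_rng(0)
    vec = atl.median_values(63.0) + rng.normal(0, 0.05, atl.template.n_pixels)
    m = BMDMap(atl.template.to_raster(vec), atl.template.mask,
               atl.template.spacing, atl.template.landmarks)
    ages, rmse, _ = D.rmse_curve(m, atl, age_step=0.5)
    naive = np.array([
        np.sqrt(np.mean((vec - atl.median_values(float(a))) ** 2))
        for a in ages
    ])
    np.testing.assert_allclose(rmse, naive, atol=1e-12)


def test_low_coverage_refused(tiny_setup):
    atl = tiny_setup["atlas"]
    m = atl.median_map(70.0)
    vec = m.values[atl.template.mask]
    vec[: int(0.1 * len(vec))] = np.nan
    m.values[atl.template.mask] = vec
    with pytest.raises(CoverageError):
        D.estimate_dba(m, atl)


def test_dba_self_consistency_and_ties(tiny_setup):
    atl = tiny_setup["atlas"]
    for age in (35.0, 55.0, 72.5, 90.0):
        res = D.estimate_dba(atl.median_map(age), atl)
        assert res.dba == pytest.approx(age, abs=0.1 + 1e-9)
        assert res.rmse_min == 0.0
    # endpoints are flagged
    res = D.estimate_dba(atl.median_map(20.0), atl)
    assert res.boundary_hit and res.dba == 20.0


def test_uniform_bmd_loss_ages_the_bone(tiny_setup):
    atl = tiny_setup["atlas"]
    m = atl.median_map(70.0)
    m.values = m.values * 0.9
    res = D.estimate_dba(m, atl)
    assert res.dba > 70.0


def test_monotone_perturbation(tiny_setup):
    # uniformly lowering BMD never rejuvenates the estimate
    atl = tiny_setup["atlas"]
    base = atl.median_map(65.0)
    last = -np.inf
    for drop in (0.0, 0.01, 0.03, 0.06):
        m = base.copy()
        m.values = m.values - drop
        d = D.estimate_dba(m, atl).dba
        assert d >= last - 1e-9
        last = d


def test_dba_oracle_equivalence_random_subjects(tiny_setup):
    # grid argmin equals exhaustive minimisation at the same resolution
    atl = tiny_setup["atlas"]
    rng = np.random.default_rng(1)
    for _ in range(50):
        vec = atl.median_values(rng.uniform(30, 90)) \
            + rng.normal(0, 0.05, atl.template.n_pixels)
        m = BMDMap(atl.template.to_raster(vec), atl.template.mask,
                   atl.template.spacing, atl.template.landmarks)
        res = D.estimate_dba(m, atl)
        k = int(np.argmin(res.rmse))
        assert res.dba == res.ages[k]
        assert res.rmse_min == res.rmse[k]


def test_dba_tracks_true_bone_age(ref_setup):
    # a low-noise subject 10 years older in bone age reads ~10 years old
    from dbatlas.shapereg import warp_to_template
    from dbatlas.simdata import GroundTruth, SimConfig, simulate_subject

    atl = ref_setup["atlas"]
    gt = GroundTruth(SimConfig(grid_shape=(96, 72), quantile_offset_sd=0.05,
                               pixel_noise_sd=0.02, seed=30))
    errs = []
    for s in range(5):
        m = simulate_subject(gt, 65.0, seed=100 + s, bone_age_offset=10.0,
                             quantile_offset=0.0)
        w = warp_to_template(m, gt.template)
        errs.append(D.estimate_dba(w, atl).dba - 65.0)
    assert np.median(errs) == pytest.approx(10.0, abs=1.5)


def test_dba_correlates_with_t_score(ref_setup):
    # over a cohort spanning the declining ages, bone age and the FN T-score
    # are strongly, negatively, linearly related
    from dbatlas import atlas as A
    from dbatlas import evalrisk as E

    atl = ref_setup["atlas"]
    tpl = atl.template
    cohort = ref_setup["cohort"]
    ages = cohort["age_years"].to_numpy()
    sel = np.flatnonzero(ages >= 45)[:400]
    ref = A.build_reference(ref_setup["warped"], ages, tpl)
    dbas, tsc = [], []
    for i in sel:
        w = ref_setup["warped"][i]
        dbas.append(D.estimate_dba(w, atl).dba)
        tsc.append(A.roi_summary(w, tpl, ref, age=float(ages[i]))["FN"].t_score)
    out = E.correlations(np.asarray(dbas), ages[sel], t_scores=np.asarray(tsc))
    assert out["dba_tscore"]["r"] < -0.7


def test_precision_hand_examples():
    res = D.precision([(80.0, 80.0), (62.0, 62.0)])
    assert res.cv_percent == 0.0 and res.mean_bias == 0.0

    res = D.precision([(80.0, 82.0)])
    assert res.cv_percent == pytest.approx(1.746, abs=5e-4)
    assert res.mean_bias == -2.0

    with pytest.raises(ValueError):
        D.precision([(1.0, -1.0)])


def test_repeat_noise_raises_cv(tiny_setup):
    # doubling the repeat noise must not shrink the DBA coefficient of
    # variation (Monte-Carlo monotonicity on the generator)
    from dataclasses import replace
    from dbatlas.shapereg import warp_to_template
    from dbatlas.simdata import SimConfig, simulate_cohort, simulate_repeat_pair

    atl = tiny_setup["atlas"]
    cvs = []
    for scale in (1.0, 2.0):
        cfg = SimConfig(grid_shape=(64, 48), n_subjects=10, seed=33,
                        age_range=(60, 80), repeat_noise_sd=0.03 * scale,
                        landmark_jitter_sd=0.0, reposition_scale_sd=0.0,
                        reposition_rot_sd=0.0, reposition_shift_sd=0.0)
        _, _, gt = simulate_cohort(cfg)
        pairs = []
        for i in range(10):
            pair = simulate_repeat_pair(gt, i, seed=50 + i)
            d1 = D.estimate_dba(warp_to_template(pair.first, gt.template), atl).dba
            d2 = D.estimate_dba(warp_to_template(pair.second, gt.template), atl).dba
            pairs.append((d1, d2))
        cvs.append(D.precision(pairs).cv_percent)
    assert cvs[0] > 0.0
    assert cvs[1] >= cvs[0]
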