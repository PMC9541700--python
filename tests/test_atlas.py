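"""Quantile atlas estimation, CDF inversion, calibration, ROI scores."""
import numpy as np
import pytest
from scipy import stats

from dbatlas import atlas as A
from dbatlas.core import BMDMap, ConfigurationError
from dbatlas.simdata import true_median_map


def test_constant_cohort_gives_constant_quantiles():
    ages = np.linspace(25, 90, 60)
    values = np.full((60, 5), 0.9)
    q, neff = A.fit_quantiles(values, ages, age_grid=np.arange(25, 91, 5.0),
                              levels=np.linspace(0.1, 0.9, 9))
    np.testing.assert_allclose(q, 0.9, atol=1e-12)
    assert np.all(neff > 0)


def test_gaussian_recovery_at_scale():
    # pixel values ~ N(mu(age), sigma): the fitted 0.5 level recovers mu to
    # 2% and Q(0.84)-Q(0.5) recovers sigma to 15% at n = 2000
    rng = np.random.default_rng(1)
    n, sigma = 2000, 0.08
    ages = rng.uniform(20, 97, n)
    mu = 1.0 - 0.004 * np.maximum(ages - 45, 0.0)
    values = mu[:, None] + sigma * rng.standard_normal((n, 4))
    grid = np.arange(30.0, 91.0, 5.0)
    levels = A.DEFAULT_LEVELS
    q, _ = A.fit_quantiles(values, ages, age_grid=grid, levels=levels)
    mu_grid = 1.0 - 0.004 * np.maximum(grid - 45, 0.0)
    l50 = np.searchsorted(levels, 0.5)
    l84 = np.searchsorted(levels, 0.84)
    assert np.max(np.abs(q[:, :, l50] - mu_grid) / mu_grid) < 0.02
    # scale recovery: the per-pixel spread, averaged over the age grid
    # (a single (pixel, age) cell has ~7% Monte-Carlo SE at this n)
    spread = (q[:, :, l84] - q[:, :, l50]).mean(axis=1)
    expected = sigma * stats.norm.ppf(0.84)
    assert np.max(np.abs(spread - expected) / expected) < 0.15


def test_monotone_rearrangement_fixes_crossings():
    q = np.array([[[0.5, 0.4, 0.6, 0.55]]])
    out = A.monotone_rearrange(q, axis=2)
    assert np.all(np.diff(out, axis=2) >= 0)


def test_atlas_monotone_in_levels(tiny_setup):
    assert np.all(np.diff(tiny_setup["atlas"].Q, axis=2) >= 0)


def test_median_map_interpolation(tiny_setup):
    atl = tiny_setup["atlas"]
    g = atl.age_grid
    exact = atl.median_values(float(g[10]))
    np.testing.assert_array_equal(exact, atl.Q[:, 10, 49].astype(float))
    mid = atl.median_values(float((g[10] + g[11]) / 2))
    np.testing.assert_allclose(
        mid, (atl.Q[:, 10, 49].astype(float) + atl.Q[:, 11, 49]) / 2, rtol=1e-7)
    with pytest.raises(ValueError):
        atl.median_map(110.0)


def test_median_trajectory_recovers_truth():
    # a 2000-subject template-space cohort: the fitted 0.5-level surface
    # tracks the generator's median surface to 3% over ages 45-90
    from dbatlas.simdata import GroundTruth, SimConfig, simulate_subject

    cfg = SimConfig(grid_shape=(64, 48), seed=21).noise_free()
    from dataclasses import replace
    cfg = replace(cfg, pixel_noise_sd=0.02, quantile_offset_sd=1.0,
                  bone_age_offset_sd=7.0)
    gt = GroundTruth(cfg)
    rng = np.random.default_rng(22)
    ages = rng.uniform(20, 97, 2000)
    values = np.stack([
        simulate_subject(gt, float(a), rng=np.random.default_rng(s)).in_mask()
        for s, a in enumerate(ages)
    ])
    grid = np.arange(20.0, 97.1, 1.0)
    q, _ = A.fit_quantiles(values, ages, age_grid=grid)
    coords = gt.template.pixel_coords_mm()
    l50 = np.searchsorted(A.DEFAULT_LEVELS, 0.5)
    check = (grid >= 45) & (grid <= 90)
    worst = 0.0
    for j in np.flatnonzero(check):
        tru = gt.median_values(coords, float(grid[j]))
        worst = max(worst, float(np.max(np.abs(q[:, j, l50] - tru) / tru)))
    assert worst < 0.03


def test_pixel_cdf_contracts(tiny_setup):
    atl = tiny_setup["atlas"]
    med = atl.median_values(60.0)
    u = atl.cdf_values(med, 60.0)
    np.testing.assert_allclose(u, 0.5, atol=0.015)
    assert A.pixel_cdf(atl, 3, 60.0, float(med[3])) == pytest.approx(0.5, abs=0.01)
    low = atl.Q[:, :, 0].min() - 1.0
    assert A.pixel_cdf(atl, 3, 60.0, low) == 0.005
    high = atl.Q[:, :, -1].max() + 1.0
    assert A.pixel_cdf(atl, 3, 60.0, high) == 0.995


def test_pixel_cdf_gaussian_oracle():
    rng = np.random.default_rng(2)
    n = 4000
    ages = rng.uniform(20, 97, n)
    values = 0.9 + 0.08 * rng.standard_normal((n, 3))
    grid = np.arange(20.0, 97.1, 2.0)
    q, neff = A.fit_quantiles(values, ages, age_grid=grid)
    u_1sigma = []
    for pix in range(3):
        qa = q[pix, len(grid) // 2, :]
        u_1sigma.append(np.interp(0.9 + 0.08, qa, A.DEFAULT_LEVELS))
    np.testing.assert_allclose(u_1sigma, 0.8413, atol=0.03)


def test_atlas_roundtrip_hdf5(tmp_path, tiny_setup):
    atl = tiny_setup["atlas"]
    path = tmp_path / "atlas.h5"
    atl.save(path)
    back = A.PixelQuantileAtlas.load(path)
    np.testing.assert_array_equal(back.Q, atl.Q)
    np.testing.assert_array_equal(back.template.mask, atl.template.mask)
    assert back.bandwidth == atl.bandwidth
    assert set(back.template.rois) == set(atl.template.rois)


def test_calibration_identity():
    rng = np.random.default_rng(3)
    a = rng.normal(0.9, 0.1, (500, 20))
    cal = A.fit_quantile_match_calibration(a, a)
    np.testing.assert_allclose(cal.slope, 1.0, atol=1e-9)
    np.testing.assert_allclose(cal.intercept, 0.0, atol=1e-9)


def test_calibration_recovers_injected_transform():
    rng = np.random.default_rng(4)
    a = rng.normal(0.9, 0.1, (1000, 30))
    b = (a - 0.05) / 1.1          # so that a = 1.1 b + 0.05
    cal = A.fit_quantile_match_calibration(a, b)
    np.testing.assert_allclose(cal.slope, 1.1, rtol=0.02)
    np.testing.assert_allclose(cal.intercept, 0.05, atol=0.002)
    # idempotence: calibrating already-matched data is the identity
    cal2 = A.fit_quantile_match_calibration(a, cal.apply(b))
    np.testing.assert_allclose(cal2.slope, 1.0, atol=1e-6)
    np.testing.assert_allclose(cal2.intercept, 0.0, atol=1e-6)


def test_calibration_reduces_ks_distance():
    rng = np.random.default_rng(5)
    a = rng.normal(0.9, 0.1, (800, 10))
    b = rng.normal(0.75, 0.13, (800, 10))
    cal = A.fit_quantile_match_calibration(a, b)
    bc = cal.apply(b)
    for p in range(10):
        before = stats.ks_2samp(a[:, p], b[:, p]).statistic
        after = stats.ks_2samp(a[:, p], bc[:, p]).statistic
        assert after < before


def test_calibration_zero_variance_flagged():
    a = np.random.default_rng(6).normal(0.9, 0.1, (200, 2))
    b = a.copy()
    b[:, 1] = 0.8
    cal = A.fit_quantile_match_calibration(a, b)
    assert not cal.flagged[0] and cal.flagged[1]
    assert cal.slope[1] == 1.0


def test_roi_scores(tiny_setup):
    atl, tpl = tiny_setup["atlas"], tiny_setup["gt"].template
    ref = A.build_reference(tiny_setup["warped"],
                            tiny_setup["cohort"]["age_years"].to_numpy(), tpl)
    young_map = tpl.to_raster(np.full(tpl.n_pixels, np.nan))
    # a map equal to the young FN mean everywhere has FN T-score 0
    m = BMDMap(tpl.to_raster(np.full(tpl.n_pixels, ref.young_mean["FN"])),
               tpl.mask, tpl.spacing, tpl.landmarks, {"age_years": 30.0})
    s = A.roi_summary(m, tpl, ref)
    assert s["FN"].t_score == pytest.approx(0.0, abs=1e-9)
    # shifting uniformly by one young SD raises the T-score by one
    m2 = BMDMap(m.values + ref.young_sd["FN"], tpl.mask, tpl.spacing,
                tpl.landmarks, {"age_years": 30.0})
    s2 = A.roi_summary(m2, tpl, ref)
    assert s2["FN"].t_score - s["FN"].t_score == pytest.approx(1.0, abs=0.01)
    # a map equal to the age-conditional mean has Z-score 0
    m3 = BMDMap(tpl.to_raster(np.full(tpl.n_pixels, ref.age_mean("TOT", 70.0))),
                tpl.mask, tpl.spacing, tpl.landmarks, {"age_years": 70.0})
    s3 = A.roi_summary(m3, tpl, ref)
    assert s3["TOT"].z_score == pytest.approx(0.0, abs=1e-9)


def test_atlas_self_consistency(tiny_setup):
    # the atlas's own median maps sit at quantile 0.5 of the atlas
    atl = tiny_setup["atlas"]
    for age in (40.0, 60.0, 80.0):
        u = atl.cdf_values(atl.median_values(age), age)
        assert np.median(np.abs(u - 0.5)) < 0.01


def test_fit_quantiles_rejects_bad_inputs():
    with pytest.raises(ConfigurationError):
        A.fit_quantiles(np.zeros((10, 3)), np.zeros(5))
    with pytest.raises(ConfigurationError):
        A.fit_quantiles(np.zeros((10, 3)), np.zeros(10), bandwidth=0.0)
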