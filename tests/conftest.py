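"""Shared fixtures: a small-grid reference cohort/atlas built once per session.

Two atlas scales are used. ``tiny_setup`` (64×48 grid, 160 subjects) keeps
unit tests fast; ``ref_setup`` (96×72 grid, 1600 subjects) is the reference
population for the bone-age and pattern-localisation checks, where atlas
sampling noise must be small relative to the effects under test.
"""
import numpy as np
import pytest
from hypothesis import settings

from dbatlas import atlas as atlas_mod
from dbatlas.shapereg import warp_to_template
from dbatlas.simdata import GroundTruth, SimConfig, simulate_cohort

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


def _build(config, age_step):
    maps, cohort, gt = simulate_cohort(config)
    warped = [warp_to_template(m, gt.template) for m in maps]
    grid = np.arange(20.0, 97.0 + 1e-9, age_step)
    atl = atlas_mod.fit_atlas(warped, cohort["age_years"].to_numpy(),
                              gt.template, bandwidth=5.0, age_grid=grid)
    return {"maps": maps, "warped": warped, "cohort": cohort, "gt": gt,
            "atlas": atl}


@pytest.fixture(scope="session")
def tiny_setup():
    return _build(SimConfig(grid_shape=(64, 48), n_subjects=160, seed=7),
                  age_step=1.0)


@pytest.fixture(scope="session")
def ref_setup():
    return _build(SimConfig(grid_shape=(96, 72), n_subjects=1600, seed=11),
                  age_step=0.5)


@pytest.fixture()
def noise_free_gt():
    cfg = SimConfig(grid_shape=(64, 48), seed=3).noise_free()
    return GroundTruth(cfg)
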