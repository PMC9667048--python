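"""Shared fixtures: small synthetic cohorts generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from petdx.preprocess import global_scale, smooth
from petdx.synth import (
    SyntheticCohortSpec,
    default_cohort_spec,
    default_topographies,
    make_toy_atlas,
    simulate_cohort,
)

#: pattern-identification (leakage) counts used throughout
DERIVATION_COUNTS = {"AD": 20, "DLB": 20, "FTD": 10, "NC": 29}


def preprocess_all(volumes, fwhm_mm=10.0):
    return [global_scale(smooth(v, fwhm_mm))[0] for v in volumes]


@pytest.fixture(scope="session")
def small_atlas():
    return make_toy_atlas((16, 16, 16), n_rois=8, seed=3)


@pytest.fixture(scope="session")
def small_cohort(small_atlas):
    """Low-noise 8-per-class cohort on a 16^3 grid, preprocessed."""
    spec = SyntheticCohortSpec(
        n_per_class={"AD": 8, "DLB": 8, "FTD": 8, "NC": 8},
        grid_shape=(16, 16, 16),
        n_rois=8,
        global_scale_sd=0.1,
        noise_sd=0.02,
        seed=3,
    )
    volumes, table = simulate_cohort(
        spec,
        default_topographies(),
        small_atlas,
        leakage_per_class={"AD": 4, "DLB": 4, "FTD": 4, "NC": 4},
    )
    return preprocess_all(volumes), table, small_atlas


@pytest.fixture(scope="session")
def default_cohort():
    """The full study-sized cohort (63/79/23/41) at the generator defaults."""
    spec = default_cohort_spec(seed=7)
    atlas = make_toy_atlas(spec.grid_shape, spec.n_rois, spec.seed, spec.voxel_size_mm)
    volumes, table = simulate_cohort(
        spec, default_topographies(), atlas, leakage_per_class=DERIVATION_COUNTS
    )
    return preprocess_all(volumes), table, atlas


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
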