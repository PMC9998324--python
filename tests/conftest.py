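"""Shared fixtures: small, fast synthetic volumes and cohorts.

Everything is generated at test time; grids are kept small (sub-clinical
resolution) so the whole suite runs quickly on one CPU.
"""

import numpy as np
import pytest

from cinetfc.cohort import (CohortConfig, DegradationSpec, PhantomGrid,
                            degrade_segmentation, iter_cohort,
                            rasterize_phantom, volume_profile)


def small_grid(**kw) -> PhantomGrid:
    defaults = dict(shape=(96, 96), n_slices=10,
                    in_plane_spacing_mm=(2.0, 2.0), slice_thickness_mm=8.0)
    defaults.update(kw)
    return PhantomGrid(**defaults)


def small_cohort_config(n_subjects=12, seed=11, **kw) -> CohortConfig:
    defaults = dict(n_subjects=n_subjects, seed=seed, grid_shape=(96, 96),
                    n_slices=10, in_plane_spacing_range_mm=(1.9, 2.1),
                    n_phases_range=(12, 16))
    defaults.update(kw)
    return CohortConfig(**defaults)


@pytest.fixture(scope="session")
def phantom_pair():
    """One reference volume and its default-degraded counterpart."""
    grid = small_grid()
    lv = volume_profile(120.0, 50.0, 14, 0.4)
    rv = volume_profile(150.0, 70.0, 14, 0.4)
    ref = rasterize_phantom(lv, rv, grid)
    specs = {s: DegradationSpec(s, 0.05) for s in ("LV", "RV")}
    auto = degrade_segmentation(ref, specs, seed=42)
    return ref, auto


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-subject cohort with references, truths and degraded volumes."""
    out = []
    for i, rec in enumerate(iter_cohort(small_cohort_config())):
        specs = {s: DegradationSpec(s, 0.05) for s in ("LV", "RV")}
        auto = degrade_segmentation(rec.reference, specs, seed=1000 + i)
        out.append((rec, auto))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
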