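import numpy as np
import pytest

from georadiomics import (
    CohortConfig,
    PhantomConfig,
    default_roi_set,
    extract_cohort_tables,
    generate_cohort,
    generate_phantom,
    rasterize,
)


@pytest.fixture(scope="session")
def phantom_sample():
    """One lesioned phantom with healthy-bone points (seed 0)."""
    cfg = PhantomConfig(seed=0, n_lesions=3, n_healthy_points=4)
    return generate_phantom(cfg)


@pytest.fixture(scope="session")
def phantom_rois(phantom_sample):
    """Five representative ROI masks on the phantom: varied shapes/sizes."""
    specs = {s.name: s for s in default_roi_set()}
    picks = ["SP15", "SP20", "SP30", "CY20", "CY50x30"]
    grid = phantom_sample.volume.grid
    bm = [p for p in phantom_sample.points if p.label.value == "BM"][0]
    hb = [p for p in phantom_sample.points if p.label.value == "HB"][0]
    centers = [bm.position, hb.position, bm.position, hb.position, bm.position]
    return [
        (name, rasterize(specs[name], center, grid))
        for name, center in zip(picks, centers)
    ]


@pytest.fixture(scope="session")
def cohort_tables():
    """Feature tables (9 ROIs + 4 ensembles) for a small two-arm cohort."""
    cfg = CohortConfig(phantom=PhantomConfig(seed=0))
    samples = generate_cohort(cfg, n_patients=24, bm_fraction=0.5, master_seed=0)
    return extract_cohort_tables(samples)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
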