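"""Shared fixtures: small synthetic datasets with known ground truth."""

import numpy as np
import pytest

from metabodiv import (NoiseModel, TruthConfig, align_peaklists,
                       generate_truth, simulate_peaklists)


@pytest.fixture(scope="session")
def small_truth():
    """~350-formula truth set with an old/new contrast."""
    cfg = TruthConfig(n_core=300, accessory={"old": 30, "new": 20})
    return generate_truth(cfg, seed=11)


@pytest.fixture(scope="session")
def small_study(small_truth):
    """Peak lists + aligned matrix for 8 old / 12 new strains, one fraction."""
    noise = NoiseModel(mass_noise_ppm=0.1, intensity_cv=0.05,
                       dropout_prob=0.02, n_noise_peaks=15)
    pls, descs = simulate_peaklists(small_truth, noise,
                                    {"old": 8, "new": 12}, seed=12)
    matrix = align_peaklists(pls, tol_ppm=1.0)
    return {"truth": small_truth, "peaklists": pls, "descriptors": descs,
            "matrix": matrix}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
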