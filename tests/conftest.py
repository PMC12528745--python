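"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

import gliofuzz as gf


def ellipsoid(shape, center, axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    return sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, axes)) <= 1


def make_phantom(seed: int, lesion_boost: float = 0.3, with_lesion: bool = True):
    """4-channel brain phantom with an optional uniformly bright lesion.

    Lesion contrast is ~+3 sigma over the tissue texture+noise spread.
    Returns (volume, brain_mask, lesion_mask).
    """
    shape = (32, 32, 16)
    rng = np.random.default_rng(seed)
    brain = ellipsoid(shape, (16, 16, 8), (13, 13, 6.5))
    tissue = np.where(
        brain, 0.5 + 0.08 * ndimage.gaussian_filter(rng.standard_normal(shape), 2), 0.0
    )
    lesion = np.zeros(shape, dtype=bool)
    enhanced = tissue.copy()
    if with_lesion:
        center = (
            14 + rng.integers(0, 4),
            14 + rng.integers(0, 4),
            7 + rng.integers(0, 2),
        )
        lesion = ellipsoid(shape, center, (4, 4, 3)) & brain
        enhanced[lesion] += lesion_boost
    volume = np.stack([tissue, enhanced, tissue, enhanced])
    noise = 0.03 * rng.standard_normal(volume.shape)
    return volume + noise * brain, brain, lesion


@pytest.fixture(scope="session")
def desk_cohort() -> gf.Cohort:
    """The default desk-scale study cohort: 80 train / 20 test, seed 0."""
    return gf.generate_cohort(gf.CohortSpec.desk(seed=0))


@pytest.fixture(scope="session")
def mini_cohort() -> gf.Cohort:
    """Tiny 20-case cohort on 16^3 volumes for fast training-path tests."""
    spec = gf.CohortSpec(
        n_hgg=12,
        n_lgg=8,
        split_counts={"HGG": (9, 0, 3), "LGG": (6, 0, 2)},
        shape=(16, 16, 16),
        seed=7,
    )
    return gf.generate_cohort(spec)


@pytest.fixture(scope="session")
def tied_bank_relu():
    """A fixed layer-tied kernel bank + unit ReLU slopes."""
    rng = np.random.default_rng(11)
    spec = gf.NetworkSpec()
    genes = [[gf.FilterGene(*rng.random(2))] for _ in spec.channels]
    return gf.build_kernel_bank(genes, spec), gf.ReLUParams()
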