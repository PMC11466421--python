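"""Shared fixtures: phantom cohorts at two scales and fitted models.

The expensive artifacts (the full-scale phantom, its preprocessed stack,
the 20-component NMF fit, and a fitted null-effect cohort) are session
scoped so every test that needs them shares one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from msinmf import (
    BinGrid,
    fit_nmf,
    preprocess,
    stack_cohort,
    tissue_masks_from_stack,
    unstack_maps,
)
from msinmf.synthetic import PhantomConfig, make_cohort, make_ground_truth

STANDARD_GRID = BinGrid(600.0, 2000.0, 0.05)
TRUNCATE_AT = 1100.0
PHANTOM_SEED = 1
NMF_MAX_ITER = 200  # past the objective plateau at phantom scale
PHANTOM_PATCH_W = 10  # patch width matched to the 36-48 px phantom rasters


def tiny_config(**overrides) -> PhantomConfig:
    """A 4-dataset, 6-component phantom for fast structural tests."""
    kwargs = dict(
        n_datasets=4,
        n_cph=2,
        shapes=((24, 24), (24, 20), (20, 24), (20, 20)),
        m_true=6,
        n_rings=2,
        seed=0,
    )
    kwargs.update(overrides)
    return PhantomConfig(**kwargs)


@pytest.fixture(scope="session")
def tiny_phantom():
    return make_cohort(tiny_config())


@pytest.fixture(scope="session")
def tiny_stack(tiny_phantom):
    datasets, _gt = tiny_phantom
    cohort = [preprocess(d, BinGrid(600.0, 2000.0, 0.5), mz_cut=TRUNCATE_AT) for d in datasets]
    return stack_cohort(cohort)


@pytest.fixture(scope="session")
def default_gt():
    return make_ground_truth(PhantomConfig(seed=PHANTOM_SEED))


@pytest.fixture(scope="session")
def phantom_cohort():
    return make_cohort(PhantomConfig(seed=PHANTOM_SEED))


@pytest.fixture(scope="session")
def stacked(phantom_cohort):
    datasets, _gt = phantom_cohort
    cohort = [preprocess(d, STANDARD_GRID, mz_cut=TRUNCATE_AT) for d in datasets]
    return stack_cohort(cohort)


@pytest.fixture(scope="session")
def nmf20(stacked):
    return fit_nmf(stacked, 20, max_iter=NMF_MAX_ITER, seed=PHANTOM_SEED, tol=0)


@pytest.fixture(scope="session")
def fitted_maps(stacked, nmf20):
    maps = unstack_maps(stacked, nmf20.z)
    masks = tissue_masks_from_stack(stacked)
    return maps, masks, stacked.class_labels


@pytest.fixture(scope="session")
def null_fitted_maps():
    """Maps fitted on a cohort with no class effect (effect = 1.0)."""
    cfg = PhantomConfig(seed=5, effect=1.0)
    datasets, _gt = make_cohort(cfg)
    cohort = [preprocess(d, STANDARD_GRID, mz_cut=TRUNCATE_AT) for d in datasets]
    S = stack_cohort(cohort)
    F = fit_nmf(S, cfg.m_true, max_iter=NMF_MAX_ITER, seed=5, tol=0)
    return unstack_maps(S, F.z), tissue_masks_from_stack(S), S.class_labels
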