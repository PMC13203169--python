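"""Shared fixtures: phantom cohorts and trained desk-scale networks.

Training fixtures are session-scoped so the segmentation-quality,
ablation and classifier checks share one set of trained models.
"""

import numpy as np
import pytest

import shouldermorph.celunet as cu
from shouldermorph.arthronet import CaseLabels, train_classifier
from shouldermorph.phantoms import generate_cohort
from shouldermorph.reconstruct import extract_gh_region

SEG_SEEDS = (0, 1, 2)
CLS_SEEDS = (0, 1, 2)


@pytest.fixture(scope="session")
def easy_seg_cohort():
    """25 low-noise phantoms on a 24^3 grid at 2 mm: 15 train / 5 val / 5 test."""
    cases = generate_cohort(25, seed=11, grid_shape=(24, 24, 24),
                            spacing=(2.0, 2.0, 2.0), noise_sd=10.0)
    return cases[:15], cases[15:20], cases[20:]


def _train_seg(cohort, seed, edge_branch=True):
    train, val, _ = cohort
    arch = cu.ArchConfig(depth=3, base_channels=4, edge_branch=edge_branch)
    return cu.train_segmentation(train, val, arch=arch, max_epochs=24,
                                 patience=8, lr=3e-3, seed=seed)


@pytest.fixture(scope="session")
def trained_seg_models(easy_seg_cohort):
    """Full CEL-UNet trained on the easy cohort, one model per seed."""
    return {s: _train_seg(easy_seg_cohort, s) for s in SEG_SEEDS}


@pytest.fixture(scope="session")
def trained_seg_ablations(easy_seg_cohort):
    """No-edge-branch ablation under the same budget and seeds."""
    return {s: _train_seg(easy_seg_cohort, s, edge_branch=False) for s in SEG_SEEDS}


def make_cls_cohort(seed, n=80, label_noise_p=0.0, balance_implant=False):
    """Phantom cohort on a 32^3 grid at 1.5 mm with full-grid GH crops."""
    cases = generate_cohort(n, seed=seed, grid_shape=(32, 32, 32),
                            spacing=(1.5, 1.5, 1.5), noise_sd=10.0,
                            label_noise_p=label_noise_p,
                            balance_implant=balance_implant)
    data = []
    for c in cases:
        region = extract_gh_region(c.labels, image=c.image, crop_size_mm=64.0)
        data.append((region.image_crop.data,
                     CaseLabels(c.os_grade, c.js_grade, c.hsa_grade, c.implant)))
    return data


@pytest.fixture(scope="session")
def cls_cohort():
    return make_cls_cohort(seed=21)


@pytest.fixture(scope="session")
def trained_classifiers(cls_cohort):
    """Multi-task classifiers trained on noise-free crops, one per seed."""
    train, val = cls_cohort[:48], cls_cohort[48:60]
    return {
        s: train_classifier(train, val, max_epochs=40, patience=10,
                            lr=3e-3, seed=s)
        for s in CLS_SEEDS
    }


@pytest.fixture(scope="session")
def cls_test_split(cls_cohort):
    return cls_cohort[60:]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
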