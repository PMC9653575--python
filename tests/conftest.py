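"""Shared fixtures: phantoms, and session-scoped heavy artifacts
(the trained segmentation network and the simulated validation cohort)
reused across the slower tests so each is built exactly once."""

from __future__ import annotations

import numpy as np
import pytest

from petmtv.phantom import (
    CohortVariation,
    UreterSpec,
    default_phantom_spec,
    generate_phantom,
    iter_cohort,
    labeled_case,
)
from petmtv.pipeline import run_phantom_cohort
from petmtv.segmentation import TrainConfig, evaluate_dice, split_cases, train_segmentation
from petmtv.unet import UNetConfig, build_residual_unet

DESK_UNET = dict(base_channels=4, max_channels=32)


@pytest.fixture(scope="session")
def noiseless_case():
    """Stock two-lesion phantom, no blur, no noise."""
    return generate_phantom(default_phantom_spec())


@pytest.fixture(scope="session")
def noisy_case():
    """Phantom with ureter streaks, PSF blur and additive noise."""
    spec = default_phantom_spec(ureter=UreterSpec(), blur_fwhm_mm=6.0,
                                noise_sigma_suv=0.1, seed=3)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def trained_segmenter():
    """Residual U-Net trained on 50 jittered phantom CTs split 5:1:4.

    Returns (model, held-out per-organ Dice). Session-scoped: training is
    the single most expensive step of the suite.
    """
    cases = [labeled_case(c)
             for c in iter_cohort(default_phantom_spec(), 50, CohortVariation(), seed=7)]
    rng = np.random.default_rng(7)
    train, val, test = split_cases(cases, (5, 1, 4), rng)
    model = build_residual_unet(UNetConfig(**DESK_UNET), seed=7)
    cfg = TrainConfig(max_epochs=30, seed=7, val_interval=0)
    model, _ = train_segmentation(model, train, cfg)
    return model, evaluate_dice(model, test)


@pytest.fixture(scope="session")
def cohort_reports(trained_segmenter):
    """Full-pipeline MTV reports on a 100-phantom cohort with mild
    blur/noise, against ground-truth MTV."""
    model, _ = trained_segmenter
    spec = default_phantom_spec(ureter=UreterSpec(), blur_fwhm_mm=6.0,
                                noise_sigma_suv=0.1)
    return run_phantom_cohort(spec, 100, CohortVariation(), seed=11,
                              model=model, organ_source="model")
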