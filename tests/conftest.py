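"""Shared fixtures.

Unit tests run on small, fast phantoms; the learned-pipeline tests
share one session-scoped desk-scale cohort (30 training / 10 held-out
phantoms) so the cross-validated ensembles are trained exactly once
per session.
"""

from __future__ import annotations

import pytest

from legquant.landmarks import TrainConfig
from legquant.phantom import (
    PhantomSpec,
    desk_spec,
    generate_phantom,
    sample_desk_cohort,
)
from legquant.pipeline import prepare_cohort, train_all


def tiny_spec(**overrides) -> PhantomSpec:
    """A small, fast phantom: scaled-down legs on a 48x48x48 grid."""
    defaults = dict(
        grid_shape=(48, 48, 48),
        spacing_mm=(5.0, 5.0, 20.0),
        leg_center_offset_mm=60.0,
        ankle_z_mm=10.0,
        knee_z_mm=410.0,
        symphysis_z_mm=828.0,
        femoral_head_z_mm=898.0,
        sft_radius_knots=((-1.0, 18.0), (0.0, 28.0), (1.045, 36.0), (1.5, 36.0)),
        sct_thickness_knots=((-1.0, 6.0), (0.0, 9.0), (1.045, 13.0), (1.5, 13.0)),
        noise_sd=0.02,
        bias_field_amplitude=0.05,
        seed=0,
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Mid-resolution noiseless phantom with exact labels."""
    spec = PhantomSpec(
        grid_shape=(160, 80, 192),
        spacing_mm=(2.0, 2.0, 5.0),
        noise_sd=0.0,
        bias_field_amplitude=0.0,
        seed=1,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def desk_phantom():
    """One noisy desk-scale phantom (64x64 in-plane)."""
    return generate_phantom(desk_spec(seed=5))


@pytest.fixture(scope="session")
def desk_models():
    """Cross-validated ensembles trained on the desk-scale cohort.

    30 training phantoms, randomized anatomy, five folds; 10 held-out
    phantoms are returned untouched for evaluation.  Training is CPU
    scale (small encoders, few epochs) and is shared across every test
    that needs learned models.
    """
    specs = sample_desk_cohort(40, seed=11)
    truths = [generate_phantom(s) for s in specs]
    train_truths, test_truths = truths[:30], truths[30:]
    cohort = prepare_cohort(train_truths, seed=1)
    models = train_all(cohort, TrainConfig(seed=0))
    return {
        "models": models,
        "train_truths": train_truths,
        "test_truths": test_truths,
    }
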