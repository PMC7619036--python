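"""Shared fixtures: small synthetic cohorts and briefly trained models.

Fixture scales are deliberately small (few dozen subjects, a few hundred
optimiser steps) so the full suite runs on one CPU core in minutes; the
acceptance tests use their own, larger, study-scale settings.
"""

import numpy as np
import pytest

from cardiovae import point_vae, synthetic_anatomy as sa


TINY = dict(points_per_class=256)


@pytest.fixture(scope="session")
def small_cohort():
    """40 subjects, 256 points/class/phase, 30% prevalent MI."""
    return sa.generate_cohort(40, mi_fraction=0.3, seed=11, **TINY)


@pytest.fixture(scope="session")
def one_sample(small_cohort):
    return small_cohort[0]


def tiny_config(seed=0, steps=10):
    return point_vae.PointVAEConfig(
        n_input_points=256, m_coarse=32, total_steps=steps, batch_size=4,
        seed=seed)


@pytest.fixture(scope="session")
def untrained_model():
    return point_vae.PointVAE(tiny_config())


@pytest.fixture(scope="session")
def trained_tiny(small_cohort):
    """One briefly trained tiny model + its training cohort."""
    cfg = tiny_config(seed=3, steps=700)
    model, hist = point_vae.train(small_cohort, cfg)
    return model, hist, small_cohort
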