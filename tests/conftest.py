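"""Shared fixtures: small deterministic map sets and design problems."""

import numpy as np
import pytest

from ktrepro.b1_synth import (
    IDENTITY_SESSION,
    SubjectParams,
    VariabilityConfig,
    make_roi,
    normalize_b1,
    sample_session,
    sample_subject,
    simulate_coil_maps,
)
from ktrepro.grids import DEFAULT_GRID, GridSpec
from ktrepro.pulse_design import DesignConfig

SMALL_GRID = GridSpec(shape=(16, 20, 20), spacing_mm=(16.0, 16.0, 16.0))


@pytest.fixture(scope="session")
def nominal_pair():
    """Nominal-anatomy (maps, roi) at identity placement, normalized."""
    subject = SubjectParams()
    roi = make_roi(subject, DEFAULT_GRID, IDENTITY_SESSION)
    maps = normalize_b1(
        simulate_coil_maps(subject, DEFAULT_GRID, IDENTITY_SESSION), roi
    )
    return maps, roi


@pytest.fixture(scope="session")
def perturbed_pair():
    """Same subject, a different session (placement + drift + screens)."""
    subject = SubjectParams()
    sess = sample_session(1234, operator_index=2, variability=VariabilityConfig(),
                          anatomy_amplitude=0.2, anatomy_seed=7, date_years=2.0)
    roi = make_roi(subject, DEFAULT_GRID, sess)
    maps = normalize_b1(simulate_coil_maps(subject, DEFAULT_GRID, sess), roi)
    return maps, roi


@pytest.fixture(scope="session")
def random_subject_pair():
    """A sampled (non-nominal) subject at a jittered session."""
    subject = sample_subject(97)
    sess = sample_session(555, operator_index=0, variability=VariabilityConfig())
    roi = make_roi(subject, DEFAULT_GRID, sess)
    maps = normalize_b1(simulate_coil_maps(subject, DEFAULT_GRID, sess), roi)
    return maps, roi


@pytest.fixture
def design_cfg():
    return DesignConfig()


def uniform_single_channel(grid=SMALL_GRID):
    """1-channel map set with b1 identically 1 (already 'normalized')."""
    from ktrepro.b1_synth import B1MapSet, ROIMask

    data = np.ones((1,) + grid.shape, dtype=complex)
    mask = np.zeros(grid.shape, dtype=bool)
    mask[4:12, 6:14, 6:14] = True
    roi = ROIMask(grid=grid, mask=mask)
    maps = B1MapSet(grid=grid, data=data, normalized=True)
    return maps, roi
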