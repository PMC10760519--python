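"""Shared fixtures: small references and simulated cohorts."""

import pytest

from macdnm.synthetic_data import (
    EvidenceConfig,
    PedigreeConfig,
    make_reference,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_ref():
    """A 200 kb random reference shared by unit tests."""
    return make_reference(200_000, seed=11)


@pytest.fixture(scope="session")
def medium_ref():
    """A 2 Mb random reference for cohort-level tests."""
    return make_reference(2_000_000, seed=12)


@pytest.fixture(scope="session")
def control_cohort(medium_ref):
    """An artifact-free 60-trio control cohort with default settings."""
    return simulate_cohort(
        PedigreeConfig(n_control_trios=60),
        evidence_config=EvidenceConfig(reference_length=len(medium_ref)),
        seed=101,
        reference=medium_ref,
    )
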