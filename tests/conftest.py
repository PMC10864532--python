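"""Shared fixtures: small analytic DVHs, random DVH batches, a synthetic cohort."""

import numpy as np
import pytest

from lungeud.dvh import DoseVolumeHistogram
from lungeud.stats import build_feature_table
from lungeud.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture
def two_bin_dvh():
    """Half the volume at 10 Gy, half at 20 Gy."""
    return DoseVolumeHistogram("lung", [5.0, 15.0, 25.0], [0.5, 0.5])


@pytest.fixture
def uniform_dvh():
    """All volume at 10 Gy."""
    return DoseVolumeHistogram("lung", [9.0, 11.0], [1.0])


def make_random_dvh(rng, max_bins=20, min_dose=0.05):
    """Random DVH with Dirichlet volumes on an irregular dose grid.

    Representative doses stay above ``min_dose`` so the EUD dose floor is
    never active and mean-dose identities hold exactly.
    """
    n_bins = int(rng.integers(2, max_bins + 1))
    widths = rng.uniform(0.5, 5.0, n_bins)
    edges = np.concatenate([[min_dose], min_dose + np.cumsum(widths)])
    volumes = rng.dirichlet(np.ones(n_bins))
    return DoseVolumeHistogram("random", edges, volumes)


@pytest.fixture
def random_dvhs():
    """200 random DVHs on a fixed seed for property suites."""
    rng = np.random.default_rng(20240131)
    return [make_random_dvh(rng) for _ in range(200)]


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared by statistics/ML tests."""
    return generate_cohort(SyntheticConfig(seed=11, n_total=120))


@pytest.fixture(scope="session")
def default_features(default_cohort):
    return build_feature_table(default_cohort)
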