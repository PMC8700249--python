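from __future__ import annotations

import numpy as np
import pytest

from metgrade import CohortSpec, SuvVolume, generate_cohort
from metgrade.features.table import build_feature_table


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def make_volume():
    """Factory for small random SUV volumes."""

    def _make(shape=(8, 8, 6), spacing=(1.0, 1.0, 1.0), seed=0, low=0.0, high=10.0):
        r = np.random.default_rng(seed)
        return SuvVolume(values=r.uniform(low, high, shape), spacing=spacing)

    return _make


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A 20-patient phantom cohort shared by table/selection/pipeline tests."""
    out = tmp_path_factory.mktemp("cohort")
    spec = CohortSpec(n_patients=20, seed=11)
    manifest = generate_cohort(spec, out)
    return out, manifest


@pytest.fixture(scope="session")
def small_feature_table(small_cohort):
    out, manifest = small_cohort
    return build_feature_table(manifest, out)
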