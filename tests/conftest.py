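import numpy as np
import pytest

from ecgdyn import (FEATURE_NAMES, STAT_NAMES, FeatureMatrix, GroupLabel,
                    SyntheticSpec, generate_cohort)
from ecgdyn.matrix import column_name

import pandas as pd


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_gaussian_matrix(n_a: int, n_b: int, lead: str = "II",
                         seed: int = 0, shift: float = 0.0) -> FeatureMatrix:
    """A valid 240-column single-lead feature matrix of Gaussian noise.

    ``shift`` moves group-a column means, making the groups separable.
    """
    rng = np.random.default_rng(seed)
    cols = [column_name(lead, f, m, s)
            for f in FEATURE_NAMES for m in range(4) for s in STAT_NAMES]
    data = rng.standard_normal((n_a + n_b, len(cols)))
    data[:n_a] += shift
    ids = pd.Index([f"R{i:03d}" for i in range(n_a + n_b)], name="record_id")
    groups = pd.Series(["HC"] * n_a + ["MI"] * n_b, index=ids, name="group")
    return FeatureMatrix(
        data=pd.DataFrame(data, index=ids, columns=cols),
        groups=groups,
    )


@pytest.fixture(scope="session")
def tiny_cohort():
    """Two-class, two-lead, 10-s cohort for structural tests."""
    spec = SyntheticSpec(
        n_per_class={GroupLabel.HC: 2, GroupLabel.MI: 2},
        leads=("II", "V2"), seed=7,
    )
    records, manifest = generate_cohort(spec)
    return records, manifest
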