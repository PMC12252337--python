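import numpy as np
import pandas as pd
import pytest

from sleepshift import (
    DatasetTable,
    SyntheticConfig,
    generate_feature_pair,
    generate_raw_session,
)
from sleepshift.types import META_COLUMNS


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_table(dataset_id, n_users=4, sessions=6, n_features=3, seed=0,
               label_rule=None):
    """A small hand-rolled feature table with both classes present."""
    r = np.random.default_rng(seed)
    rows = []
    names = [f"f{j}" for j in range(n_features)]
    for u in range(n_users):
        for s in range(sessions):
            x = r.normal(size=n_features)
            if label_rule is None:
                label = "high" if x[0] > 0 else "low"
            else:
                label = label_rule(u, s, x)
            row = {"user_id": f"{dataset_id}_u{u}", "dataset_id": dataset_id,
                   "session_index": s, "label": label}
            row.update(dict(zip(names, x)))
            rows.append(row)
    return DatasetTable(pd.DataFrame(rows, columns=META_COLUMNS + names))


@pytest.fixture
def small_tables():
    return make_table("A", n_users=3, seed=1), make_table("B", n_users=2, seed=2)


@pytest.fixture(scope="session")
def raw_session():
    return generate_raw_session(
        heart_rate_bpm=60.0, breaths_per_min=15.0, motion_level=0.3,
        duration_s=400.0, seed=7,
    )


@pytest.fixture(scope="session")
def null_pair():
    """Two synthetic datasets drawn from the same distribution (no shift)."""
    cfg = SyntheticConfig(shift_delta=0.0, seed=11)
    return generate_feature_pair(cfg)


@pytest.fixture(scope="session")
def shifted_pair():
    """A pair with a strong mean shift on 30% of the features."""
    cfg = SyntheticConfig(shift_delta=2.0, shift_fraction=0.3, seed=11)
    return generate_feature_pair(cfg)
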