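import numpy as np
import pandas as pd
import pytest

from globeseed import synth
from globeseed.core import SeedBankRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_record(**overrides) -> SeedBankRecord:
    base = dict(
        record_id="r1",
        latitude=45.0,
        longitude=10.0,
        biome="TBMF",
        measure="diversity",
        value=8.0,
        sample_area_m2=0.01,
        depth_upper_cm=0.0,
        depth_lower_cm=5.0,
        sampling_month=1,
        season=None,
    )
    base.update(overrides)
    return SeedBankRecord(**base)


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture(scope="session")
def small_world():
    """A modest synthetic world shared by read-only tests."""
    cfg = synth.default_config(n_records=200)
    records, predictors, truth = synth.generate_dataset(cfg, seed=42)
    return cfg, records, predictors, truth


@pytest.fixture(scope="session")
def strong_regression():
    """(X, y, informative names): 5 strong linear effects + 26 decoys."""
    rng = np.random.default_rng(7)
    n, p = 2000, 31
    X = pd.DataFrame(
        rng.normal(size=(n, p)), columns=[f"v{i:02d}" for i in range(p)]
    )
    beta = np.zeros(p)
    beta[:5] = [3.0, 2.8, 2.5, 2.2, 2.0]
    y = X.to_numpy() @ beta + rng.normal(size=n)
    return X, y, [f"v{i:02d}" for i in range(5)]
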