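import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mpratio.data import BioassayDataset, ReplicateRecord
from mpratio.synthetic import GeneratorConfig, generate

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def make_records(cells, controls=((10, 0),), run_id="r1"):
    """Build records from (pct, ss, n_exposed, n_dead) tuples plus controls."""
    recs = [
        ReplicateRecord(0.0, 0.0, n, d, run_id=run_id, is_control=True) for n, d in controls
    ]
    recs += [
        ReplicateRecord(ss, pct, n, d, run_id=run_id, is_control=False)
        for pct, ss, n, d in cells
    ]
    return recs


@pytest.fixture
def tiny_dataset():
    """One mixture level, four doses, clean monotone mortality, one control."""
    cells = [
        (0.0, 10.0, 10, 0),
        (0.0, 100.0, 10, 2),
        (0.0, 1000.0, 10, 7),
        (0.0, 10000.0, 10, 10),
    ]
    return BioassayDataset(make_records(cells))


@pytest.fixture(scope="session")
def synthetic_dataset():
    """Study-scale balanced synthetic dataset (6 %MP levels, 5 reps/cell)."""
    return generate(GeneratorConfig(seed=123))


@pytest.fixture(scope="session")
def unbalanced_dataset():
    """Synthetic dataset with over-replicated endpoint levels (subsampling path)."""
    return generate(GeneratorConfig(seed=123, extra_replicates=((0.0, 15), (100.0, 15))))


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
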