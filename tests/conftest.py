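import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_instance(rng, max_reads=8, max_clusters=4):
    """A random (truth, predicted) pair of partitions of the same reads."""
    n = int(rng.integers(1, max_reads + 1))
    ids = [f"s{i}" for i in range(n)]
    truth = {rid: int(rng.integers(0, max_clusters)) for rid in ids}
    pred = {rid: int(rng.integers(0, max_clusters)) for rid in ids}
    return truth, pred


@pytest.fixture
def perfect_small_dataset(rng):
    """20 strands x 10 exact copies, length 150 — a perfect-recovery fixture."""
    import gradhc as g

    design = g.generate_design(20, 150, rng)
    reads, truth = g.generate_dataset(
        design, g.ClusterSizeModel(kind="fixed", size=10), g.ErrorModel(), rng
    )
    return design, reads, truth
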