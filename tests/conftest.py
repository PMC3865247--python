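import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from shallowseq import CountExperiment

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


def make_experiment(counts: dict[str, list[int]], lengths=None,
                    genes=None) -> CountExperiment:
    """Build a tiny two-condition experiment from per-sample count lists.

    Sample names must look like ``<condition>_<replicate>``.
    """
    n = len(next(iter(counts.values())))
    genes = genes or [f"g{i}" for i in range(n)]
    cdf = pd.DataFrame(counts, index=genes, dtype=np.int64)
    if lengths is None:
        lengths = [1000] * n
    lser = pd.Series(lengths, index=genes)
    design = pd.DataFrame(
        [(s.rsplit("_", 1)[0], s.rsplit("_", 1)[1]) for s in cdf.columns],
        index=pd.Index(cdf.columns, name="sample"),
        columns=["condition", "replicate"],
    )
    return CountExperiment(cdf, lser, design)


@pytest.fixture
def tiny_experiment() -> CountExperiment:
    """12 genes x (2 conditions x 2 replicates) with zeros and a big DE gene."""
    rng = np.random.default_rng(42)
    base = rng.integers(10, 60, size=(12, 4))
    base[0] = [50000, 51000, 5, 6]  # dominant DE gene
    base[1] = [0, 0, 0, 0]          # never expressed
    base[2] = [0, 3, 1, 2]          # nearly silent
    return make_experiment(
        {s: base[:, j].tolist() for j, s in enumerate(["A_1", "A_2", "B_1", "B_2"])},
        lengths=rng.integers(500, 5000, size=12).tolist(),
    )


@pytest.fixture
def random_experiment() -> CountExperiment:
    """50 genes x 4 samples of moderately deep Poisson-ish counts."""
    rng = np.random.default_rng(7)
    mat = rng.poisson(rng.lognormal(3.0, 1.2, size=50)[:, None], size=(50, 4))
    return make_experiment(
        {s: mat[:, j].tolist() for j, s in enumerate(["A_1", "A_2", "B_1", "B_2"])},
        lengths=rng.integers(200, 8000, size=50).tolist(),
    )
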