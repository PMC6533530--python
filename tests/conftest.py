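import numpy as np
import pytest
from hypothesis import settings

from mycogrid import synth

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def small_config(**kw) -> synth.SimulationConfig:
    """A fast toy experiment: 2 runs of 8x10 blocks, 48 varieties, 600 SNPs."""
    defaults = dict(
        n_varieties=48, subgroup_sizes={"A": 16, "B": 16, "C": 16}, n_checks=2,
        n_runs=2, rows=8, cols=10, n_snps=600, n_chrom=6)
    defaults.update(kw)
    return synth.SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_experiment():
    return synth.simulate_experiment(small_config(), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
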