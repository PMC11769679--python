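import numpy as np
import pytest

import funmap
from funmap.simulation import SimulationDesign, simulate_genotypes


@pytest.fixture(scope="session")
def signal_dataset():
    """LD-structured locus (n=1000, p=80) with one strong causal SNP."""
    rng = np.random.default_rng(42)
    des = SimulationDesign(n=1000, p=80, ld_rho=0.5, seed=42)
    X = simulate_genotypes(des, rng)
    y = X[:, 17] * 0.35 + rng.standard_normal(1000)
    data = funmap.GenotypePhenotype.from_raw(X, y)
    ss = funmap.suffstats_from_individual(data)
    return data, ss, 17


@pytest.fixture(scope="session")
def small_fit(signal_dataset):
    """A converged annotation-free fit of the signal locus."""
    _, ss, _ = signal_dataset
    state, diag = funmap.fit(ss, None, funmap.ModelConfig(L=5))
    return state, diag
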