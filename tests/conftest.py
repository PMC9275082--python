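import numpy as np
import pytest

from mtlink.hetgraph import build_propagation_graph
from mtlink.pipeline import build_dataset
from mtlink.synth import SynthConfig, generate


@pytest.fixture(scope="session")
def tiny_dataset():
    """5 miRNAs x 7 targets planted-block instance with similarities."""
    cfg = SynthConfig(M=5, N=7, n_blocks=2, p_in=0.6, p_out=0.1,
                      seq_len_target=30, seed=3)
    mirnas, targets, A, *_ = generate(cfg)
    return build_dataset(mirnas, targets, A)


@pytest.fixture(scope="session")
def tiny_graph(tiny_dataset):
    ds = tiny_dataset
    return build_propagation_graph(ds.A, ds.Sm, ds.Sn, mu=0.06)


@pytest.fixture(scope="session")
def small_dataset():
    """20 x 30 planted-block instance, big enough for training sanity."""
    cfg = SynthConfig(M=20, N=30, n_blocks=2, p_in=0.5, p_out=0.05,
                      seq_len_target=40, seed=11)
    mirnas, targets, A, *_ = generate(cfg)
    return build_dataset(mirnas, targets, A)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
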