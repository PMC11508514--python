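import numpy as np
import pytest

import mitoscolia as m
from mitoscolia.data import scoliidae_modes, scoliidae_tree


@pytest.fixture(scope="session")
def ancestral():
    return m.ancestral_reference()


@pytest.fixture(scope="session")
def scoliini_order():
    return m.gene_order_preset("scoliini_like")


@pytest.fixture(scope="session")
def campsomerini_order():
    return m.gene_order_preset("campsomerini_like")


@pytest.fixture()
def fig_tree():
    return scoliidae_tree()


@pytest.fixture(scope="session")
def modes_matrix():
    return scoliidae_modes()


@pytest.fixture(scope="session")
def small_genome():
    """A deterministic simulated mitogenome used across I/O and composition tests."""
    cfg = m.SimulationConfig(seed=11, target_at=0.80, gene_order="scoliini_like")
    return m.simulate_mitogenome(cfg, genome_id="sim11")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240930)
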