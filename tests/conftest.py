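import numpy as np
import pytest

import netthermo as nt


@pytest.fixture
def k2():
    return nt.gen_named_graph("complete", 2)


@pytest.fixture
def k3():
    return nt.gen_named_graph("complete", 3)


@pytest.fixture
def p3():
    return nt.gen_named_graph("path", 3)


@pytest.fixture
def p4():
    return nt.gen_named_graph("path", 4)


@pytest.fixture
def star5():
    return nt.gen_named_graph("star", 5)


def random_graph(rng, n_min=3, n_max=40, p_min=0.1, p_max=0.9, no_isolated=False):
    """Seeded random ER graph helper for oracle-identity sweeps."""
    while True:
        n = int(rng.integers(n_min, n_max + 1))
        p = float(rng.uniform(p_min, p_max))
        g = nt.gen_er_graph(n, p, seed=int(rng.integers(2**31)))
        if not no_isolated or not g.has_isolated_nodes():
            return g


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)
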