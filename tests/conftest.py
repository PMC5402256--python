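import numpy as np
import pytest

from multilex.core import Layer, MultiplexNetwork, Vocabulary, Word


@pytest.fixture
def toy_vocab():
    return Vocabulary(["a", "b", "c", "d", "e"])


@pytest.fixture
def toy_mln(toy_vocab):
    """Two complementary layers whose union is a path a-b-c-d-e."""
    l1 = Layer("semantic", [("a", "b"), ("c", "d")])
    l2 = Layer("phonological", [("b", "c"), ("d", "e")])
    return MultiplexNetwork(toy_vocab, [l1, l2])


def random_layer(n_nodes: int, p: float, rng: np.random.Generator, name: str = "layer") -> Layer:
    """Erdos-Renyi layer over w0000..w{n-1}."""
    words = [f"w{i:04d}" for i in range(n_nodes)]
    edges = [
        (words[i], words[j])
        for i in range(n_nodes)
        for j in range(i + 1, n_nodes)
        if rng.random() < p
    ]
    return Layer(name, edges)


def random_mln(n_nodes: int, n_layers: int, p: float, seed: int) -> MultiplexNetwork:
    rng = np.random.default_rng(seed)
    words = [f"w{i:04d}" for i in range(n_nodes)]
    layers = [random_layer(n_nodes, p, rng, f"layer{k}") for k in range(n_layers)]
    return MultiplexNetwork(Vocabulary(words), layers)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
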