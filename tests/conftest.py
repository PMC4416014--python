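import random

import pytest

from mixmod import HetNet, Partition


def random_hetnet(
    rng: random.Random,
    nA: int = 8,
    nB: int = 10,
    pAA: float = 0.35,
    pAB: float = 0.25,
    pBB: float = 0.3,
    weighted: bool = True,
) -> HetNet:
    """A small random 2-HN with all three channels usually populated."""
    a = [f"a{i}" for i in range(nA)]
    b = [f"b{i}" for i in range(nB)]
    nodes = {x: "A" for x in a}
    nodes.update({x: "B" for x in b})
    net = HetNet(nodes)

    def w() -> float:
        return round(rng.uniform(0.5, 3.0), 3) if weighted else 1.0

    for i in range(nA):
        for j in range(i + 1, nA):
            if rng.random() < pAA:
                net.add_edge(a[i], a[j], w())
    for i in range(nA):
        for j in range(nB):
            if rng.random() < pAB:
                net.add_edge(a[i], b[j], w())
    for i in range(nB):
        for j in range(i + 1, nB):
            if rng.random() < pBB:
                net.add_edge(b[i], b[j], w())
    return net


def random_partition(rng: random.Random, net: HetNet, max_modules: int = 4) -> Partition:
    k = rng.randint(1, max_modules)
    return Partition({n: rng.randrange(k) for n in net.nodes})


@pytest.fixture
def toy_net() -> HetNet:
    """Three planted mixed modules over 6 A + 6 B nodes, loosely interlinked."""
    nodes = {f"a{i}": "A" for i in range(6)}
    nodes.update({f"b{i}": "B" for i in range(6)})
    edges = [
        # module 0: a0 a1 b0 b1
        ("a0", "a1", 1.0), ("a0", "b0", 1.0), ("a1", "b1", 1.0), ("b0", "b1", 1.0),
        # module 1: a2 a3 b2 b3
        ("a2", "a3", 1.0), ("a2", "b2", 1.0), ("a3", "b3", 1.0), ("b2", "b3", 1.0),
        # module 2: a4 a5 b4 b5
        ("a4", "a5", 1.0), ("a4", "b4", 1.0), ("a5", "b5", 1.0), ("b4", "b5", 1.0),
        # sparse inter-module links
        ("a1", "a2", 1.0), ("b3", "b4", 1.0), ("a5", "b0", 1.0),
    ]
    return HetNet(nodes, edges)


@pytest.fixture
def toy_partition(toy_net) -> Partition:
    return Partition({
        "a0": 0, "a1": 0, "b0": 0, "b1": 0,
        "a2": 1, "a3": 1, "b2": 1, "b3": 1,
        "a4": 2, "a5": 2, "b4": 2, "b5": 2,
    })
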