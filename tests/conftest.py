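import numpy as np
import pandas as pd
import pytest

from axonkit.arbor import ArborTree


def tree_from_edges(coords, parents):
    """Build an ArborTree from 0-based coordinate list and parent indices."""
    n = len(coords)
    coords = np.asarray(coords, float)
    if coords.shape[1] == 2:
        coords = np.column_stack([coords, np.zeros(n)])
    df = pd.DataFrame({
        "id": np.arange(1, n + 1),
        "type": np.full(n, 2),
        "x": coords[:, 0], "y": coords[:, 1], "z": coords[:, 2],
        "radius": np.full(n, 0.5),
        "parent": np.array([p + 1 if p >= 0 else -1 for p in parents]),
    })
    return ArborTree(df)


def random_binary_tree(rng, max_bifurcations=8):
    """Random binary tree with random segment lengths; unit-step chains.

    Grows by repeatedly picking a random existing node with < 2 children
    and appending a short chain to it.
    """
    coords = [(0.0, 0.0)]
    parents = [-1]
    children = {0: 0}
    n_bif = int(rng.integers(1, max_bifurcations + 1))
    # primary chain
    tips = [0]
    for _ in range(n_bif + 1 + int(rng.integers(0, 3))):
        candidates = [i for i, c in children.items() if c < 2]
        host = int(rng.choice(candidates))
        chain_len = int(rng.integers(2, 6))
        prev = host
        base = np.asarray(coords[host])
        ang = rng.uniform(0, 2 * np.pi)
        for s in range(1, chain_len + 1):
            step = rng.uniform(0.5, 2.0)
            base = base + step * np.array([np.cos(ang), np.sin(ang)])
            ang += rng.normal(0, 0.3)
            coords.append(tuple(base))
            parents.append(prev)
            children[prev] = children.get(prev, 0) + 1
            prev = len(coords) - 1
            children[prev] = 0
        tips.append(prev)
    return tree_from_edges(coords, parents)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
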