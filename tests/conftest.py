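import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from laternet.connectome import AtlasNode, Connectome


def make_atlas(n_pairs: int) -> list[AtlasNode]:
    nodes = [AtlasNode(k, f"P{k:02d}L", "L", k) for k in range(n_pairs)]
    nodes += [AtlasNode(n_pairs + k, f"P{k:02d}R", "R", k) for k in range(n_pairs)]
    return nodes


def random_connectome(rng: np.random.Generator, n_pairs: int, density: float = 0.5,
                      max_weight: float = 1.0) -> Connectome:
    n = 2 * n_pairs
    w = np.triu(rng.uniform(0.05, max_weight, (n, n)), 1)
    w *= rng.random((n, n)) < density
    w = w + w.T
    return Connectome(make_atlas(n_pairs), w)


def symmetric_connectome(rng: np.random.Generator, n_pairs: int,
                         density: float = 0.5) -> Connectome:
    """Hemispherically mirror-symmetric random connectome."""
    h = n_pairs
    intra = np.triu(rng.uniform(0.1, 1.0, (h, h)), 1)
    intra *= rng.random((h, h)) < density
    intra = intra + intra.T
    inter = np.triu(rng.uniform(0.1, 1.0, (h, h)))
    inter *= rng.random((h, h)) < density
    inter = np.triu(inter) + np.triu(inter, 1).T
    w = np.vstack([np.hstack([intra, inter]), np.hstack([inter, intra])])
    return Connectome(make_atlas(n_pairs), w)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
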