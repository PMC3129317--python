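import numpy as np
import pytest

from habitevol.io import CharacterMatrix, Phylogeny
from habitevol.simulate import simulate_yule_tree


def random_tree(rng: np.random.Generator, n_tips: int) -> Phylogeny:
    """Random binary tree with exponential branch lengths (test helper)."""
    return simulate_yule_tree(n_tips, birth_rate=1.0, seed=rng)


def random_matrix(
    rng: np.random.Generator,
    tree: Phylogeny,
    k: int,
    missing_prob: float = 0.0,
) -> CharacterMatrix:
    """Random tip states over codes 1..k; guarantees >= 2 distinct states."""
    tips = sorted(tree.tip_names)
    while True:
        codes = {
            t: 0 if rng.random() < missing_prob else int(rng.integers(1, k + 1))
            for t in tips
        }
        observed = {c for c in codes.values() if c != 0}
        if len(observed) >= 2:
            return CharacterMatrix(codes)


@pytest.fixture
def rng():
    return np.random.default_rng(20110614)


@pytest.fixture
def three_tip_tree():
    from habitevol.io import parse_newick

    return parse_newick("((A:1,B:1):1,C:2);")
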