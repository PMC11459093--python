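import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from chronophylo.synthetic import simulate_phylogeny
from chronophylo.trees import Phylogeny


@pytest.fixture
def demo_tree() -> Phylogeny:
    """Three-tip worked-example tree: ((A:1,B:1):1,C:2)."""
    return Phylogeny.from_newick("((A:1,B:1):1,C:2);")


def make_star_tree(k: int, length: float = 1.0) -> Phylogeny:
    tips = ",".join(f"t{i:02d}:{length}" for i in range(1, k + 1))
    return Phylogeny.from_newick(f"({tips});")


@pytest.fixture
def star10() -> Phylogeny:
    return make_star_tree(10)


def random_tree(seed: int, n_tips: int, ultrametric: bool = True) -> Phylogeny:
    """Seeded random tree; optionally with jittered (non-ultrametric) branches."""
    p = simulate_phylogeny(n_tips, seed)
    if ultrametric:
        return p
    rng = np.random.default_rng(seed + 10_000)
    clone = p.tree.extract_tree()
    for edge in clone.preorder_edge_iter():
        if edge.length is not None:
            edge.length = float(edge.length * rng.uniform(0.3, 1.7))
    return Phylogeny(clone)
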