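import numpy as np
import pytest

from paleodiv.bd import BDModelSpec, RateFunction
from paleodiv.phylo import Node, Phylogeny, parse_newick
from paleodiv.simulate import SimulationConfig, simulate_bd_tree, _relabel


@pytest.fixture
def tree5():
    """Five-tip asymmetric ultrametric tree used across modules."""
    return parse_newick("(((A:1,B:1):1.5,C:2.5):1,(D:2,E:2):1.5);")


@pytest.fixture
def tips5():
    return {"A": 0, "B": 1, "C": 0, "D": 2, "E": 1}


@pytest.fixture
def bt4():
    """Branching times of a 4-tip tree (crown 3 Ma)."""
    return np.array([3.0, 1.7, 0.9])


def build_two_cluster_tree(seed: int, depth: float = 2.0, stem: float = 18.0,
                           lam: float = 1.6, tips: int = 20) -> Phylogeny:
    """Two Yule subtrees joined by stems much longer than the subtree depth."""
    spec = BDModelSpec(RateFunction("constant", lam), None, 1.0, "crown_survival")
    t1 = simulate_bd_tree(spec, SimulationConfig(
        seed=seed, crown_age=depth, conditioning="n_tips", target_tips=tips,
        tip_tolerance=0.2))
    t2 = simulate_bd_tree(spec, SimulationConfig(
        seed=seed + 1000, crown_age=depth, conditioning="n_tips",
        target_tips=tips, tip_tolerance=0.2))
    root = Node()
    r1 = _relabel(t1.root, "A")
    r2 = _relabel(t2.root, "B")
    r1.length = stem
    r2.length = stem
    r1.parent = r2.parent = root
    root.children = [r1, r2]
    return Phylogeny(root)


@pytest.fixture(scope="session")
def two_cluster_tree():
    return build_two_cluster_tree(seed=3)
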