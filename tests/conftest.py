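import numpy as np
import pytest

from intronevo.model import EdgeParams, ModelParams
from intronevo.trees import SpeciesTree


@pytest.fixture
def cherry3():
    """((A,B)ab,C)root — the smallest tree with an internal edge."""
    return SpeciesTree.from_newick("((A,B)ab,C)root;")


@pytest.fixture
def tree6():
    """Fixed 6-leaf binary tree used by the calibration tests."""
    return SpeciesTree.from_newick(
        "(((A,B)ab,(C,D)cd)abcd,(E,F)ef)root;")


@pytest.fixture
def params3(cherry3):
    return ModelParams(
        pi=0.6,
        edge_params={
            "A": EdgeParams(0.8, 0.3),
            "B": EdgeParams(0.5, 0.1),
            "ab": EdgeParams(1.2, 0.4),
            "C": EdgeParams(0.3, 0.2),
        },
        shape_loss=0.8, k_gain=1, k_loss=2,
    )


def make_params(tree, rng, k_gain=1, k_loss=2, pi=None):
    edges = {tree.names[u]: EdgeParams(float(rng.uniform(0.05, 2.5)),
                                       float(rng.uniform(0.05, 0.95)))
             for u in tree.nonroot()}
    return ModelParams(
        pi=float(pi if pi is not None else rng.uniform(0.1, 0.9)),
        edge_params=edges,
        shape_gain=float(rng.uniform(0.3, 4)),
        shape_loss=float(rng.uniform(0.3, 4)),
        k_gain=k_gain, k_loss=k_loss,
    )
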