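import itertools
import math

import numpy as np
import pytest

from caenophylo.ancestral import MkModel
from caenophylo.trees import Node, Phylo


def random_rooted_tree(rng: np.random.Generator, n_leaves: int, mean_length: float = 0.5) -> Phylo:
    """Random rooted binary tree with exponential branch lengths."""
    nodes = [Node(label=f"t{i+1}", length=float(rng.exponential(mean_length)))
             for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = Node(length=float(rng.exponential(mean_length)))
        parent.add_child(a)
        parent.add_child(b)
        nodes.append(parent)
    nodes[0].length = None
    return Phylo(nodes[0])


def brute_force_loglik(tree: Phylo, character: dict, model: MkModel) -> float:
    """Likelihood by exhaustive enumeration over internal-node states."""
    internals = [n for n in tree.preorder() if not n.is_leaf]
    total = 0.0
    for assign in itertools.product(range(model.k), repeat=len(internals)):
        states = dict(zip((id(n) for n in internals), assign))
        p = model.prior[states[id(tree.root)]]
        for n in tree.preorder():
            if n is tree.root:
                continue
            child_state = character[n.label] if n.is_leaf else states[id(n)]
            p *= model.transition_matrix(n.length or 0.0)[
                states[id(n.parent)], child_state
            ]
        total += p
    return math.log(total) if total > 0 else float("-inf")


def brute_force_marginals(tree: Phylo, character: dict, model: MkModel) -> dict:
    """Node posteriors by exhaustive enumeration, keyed by clade leaf set."""
    internals = [n for n in tree.preorder() if not n.is_leaf]
    acc = {id(n): np.zeros(model.k) for n in internals}
    for assign in itertools.product(range(model.k), repeat=len(internals)):
        states = dict(zip((id(n) for n in internals), assign))
        p = model.prior[states[id(tree.root)]]
        for n in tree.preorder():
            if n is tree.root:
                continue
            child_state = character[n.label] if n.is_leaf else states[id(n)]
            p *= model.transition_matrix(n.length or 0.0)[
                states[id(n.parent)], child_state
            ]
        for n in internals:
            acc[id(n)][states[id(n)]] += p
    return {
        tree.leaf_set(n): acc[id(n)] / acc[id(n)].sum()
        for n in internals
        if acc[id(n)].sum() > 0
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
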