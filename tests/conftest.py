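import numpy as np
import pytest

from biogeodiva.areas import AreaAlphabet, TipDistribution
from biogeodiva.trees import DatedTree, TreeNode, parse_newick


@pytest.fixture
def balanced4():
    return parse_newick("((A:1,B:1):2,(C:2,D:2):1);")


@pytest.fixture
def ab_alphabet():
    return AreaAlphabet("AB")


def random_bifurcating_tree(rng: np.random.Generator, n_tips: int) -> DatedTree:
    """Random ultrametric topology by sequential tip attachment."""
    labels = [f"t{i}" for i in range(1, n_tips + 1)]
    rng.shuffle(labels)
    nodes = [TreeNode(label=labels[0]), TreeNode(label=labels[1])]
    root = TreeNode(children=list(nodes))
    for lab in labels[2:]:
        # pick a random existing node and split its branch
        target = nodes[rng.integers(len(nodes))]
        holder = TreeNode(label=target.label, children=target.children)
        target.label = None
        target.children = [holder, TreeNode(label=lab)]
        nodes.extend(target.children)
    _assign_ultrametric_lengths(root, rng)
    return DatedTree(root)


def _assign_ultrametric_lengths(root: TreeNode, rng: np.random.Generator) -> None:
    """Give every node an age consistent with a random ultrametric tree."""

    def depth(node):
        if not node.children:
            return 1
        return 1 + max(depth(c) for c in node.children)

    def set_ages(node, age):
        node.age = age
        for c in node.children:
            child_age = 0.0 if not c.children else age * rng.uniform(0.3, 0.9)
            set_ages(c, child_age)
            c.length = age - child_age

    set_ages(root, 10.0 + float(rng.uniform(0, 5)))
    root.length = 0.0


def random_tip_distribution(
    rng: np.random.Generator, tree: DatedTree, alphabet: AreaAlphabet
) -> TipDistribution:
    n = len(alphabet)
    ranges = {}
    for t in tree.tip_labels:
        ranges[t] = int(rng.integers(1, 1 << n))
    return TipDistribution(alphabet, ranges)
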