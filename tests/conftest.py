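import dendropy
import numpy as np
import pytest

from plastmark.msa_io import Alignment

ALPHABET = "ACGT-NRY"


def make_alignment(rows: dict[str, str]) -> Alignment:
    return Alignment(tuple(rows), tuple(rows.values()))


def random_alignment(
    rng: np.random.Generator, n_taxa: int, length: int, alphabet: str = ALPHABET
) -> Alignment:
    chars = np.array(list(alphabet))
    rows = {
        f"t{i}": "".join(chars[rng.integers(0, len(chars), length)])
        for i in range(n_taxa)
    }
    return make_alignment(rows)


def random_rooted_tree(
    rng: np.random.Generator, n_tips: int, scale: float = 1.0
) -> dendropy.Tree:
    """Random join topology with Exponential(1/scale) branch lengths."""
    tns = dendropy.TaxonNamespace([f"t{i}" for i in range(n_tips)])
    nodes = [dendropy.Node(taxon=tns.get_taxon(f"t{i}")) for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=nodes[0])
    tree.is_rooted = True
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            nd.edge.length = float(rng.exponential(scale))
    return tree


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def quartet_tree() -> dendropy.Tree:
    """Balanced 4-tip tree: short cherries (0.01) under long internals (1.0)."""
    nw = "((A:0.01,B:0.01):1.0,(C:0.01,D:0.01):1.0);"
    return dendropy.Tree.get(data=nw, schema="newick", rooting="force-rooted")
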