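import random

import pytest

from kmersieve.kmer_index import ReferenceGenome
from kmersieve.taxonomy import TaxNode, TaxonomyTree


@pytest.fixture
def star_tree():
    """Root 1 with species leaves 101/102 under genus nodes 11/12."""
    return TaxonomyTree(
        [
            TaxNode(1, 1, "root", "root"),
            TaxNode(11, 1, "genus", "Genericus"),
            TaxNode(12, 1, "genus", "Alterum"),
            TaxNode(101, 11, "species", "Genericus unus"),
            TaxNode(102, 11, "species", "Genericus duo"),
            TaxNode(103, 12, "species", "Alterum tres"),
        ]
    )


def random_tree(rng: random.Random, n_nodes: int) -> TaxonomyTree:
    """Random rooted tree: node i's parent drawn among nodes < i (root is 1)."""
    nodes = [TaxNode(1, 1)]
    ids = [1]
    for i in range(2, n_nodes + 1):
        nodes.append(TaxNode(i, rng.choice(ids)))
        ids.append(i)
    return TaxonomyTree(nodes)


def random_genome(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


def random_references(rng: random.Random, tree, leaves, length_range=(200, 1000)):
    return [
        ReferenceGenome(
            f"g{node}", node, (random_genome(rng, rng.randint(*length_range)),)
        )
        for node in leaves
    ]
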