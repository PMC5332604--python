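import dendropy
import numpy as np
import pandas as pd
import pytest

from evgtools.community import CommunitySpec, generate_community


def random_additive_matrix(rng, n):
    """Distance matrix from a random unrooted binary tree with positive
    branch lengths (shared oracle for tree-reconstruction tests)."""
    taxa = [f"t{i}" for i in range(n)]
    ns = dendropy.TaxonNamespace(taxa)
    nodes = []
    for t in taxa:
        nd = dendropy.Node(taxon=ns.get_taxon(t))
        nd.edge.length = float(rng.uniform(0.05, 1.0))
        nodes.append(nd)
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.edge.length = float(rng.uniform(0.05, 1.0))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)] + [parent]
    tree = dendropy.Tree(taxon_namespace=ns)
    for nd in nodes:
        tree.seed_node.add_child(nd)
    tree.is_rooted = False
    pdm = tree.phylogenetic_distance_matrix()
    mat = np.zeros((n, n))
    tx = [ns.get_taxon(t) for t in taxa]
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = pdm.patristic_distance(tx[i], tx[j])
    return tree, pd.DataFrame(mat, index=taxa, columns=taxa)


@pytest.fixture(scope="session")
def small_community():
    """A 4-genus, 3-genomes-per-genus community shared across tests."""
    spec = CommunitySpec(
        n_genera=4, genomes_per_genus=3, genome_length_bp=(12_000, 15_000), seed=7
    )
    genomes, truth = generate_community(spec)
    return spec, genomes, truth


@pytest.fixture(scope="session")
def small_sg(small_community):
    """All-against-all S_G matrix of the small community (tBLASTx-backed)."""
    from evgtools.similarity import sg_matrix

    _, genomes, _ = small_community
    return sg_matrix(genomes, candidates="all")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
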