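"""Proteomic tree construction: BIONJ on 1 - S_G distances, midpoint rooted.

BIONJ is the neighbor-joining variant of Gascuel (1997): the pair to join
minimizes the usual NJ Q-criterion, but the reduction of the distance matrix
uses variance weights, propagating a variance matrix alongside the
distances. On additive inputs it reproduces the generating tree exactly.
Trees are held as dendropy objects; Newick I/O and midpoint rooting use
dendropy.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import dendropy


def to_distance(sg: pd.DataFrame) -> pd.DataFrame:
    """Distance matrix d = 1 - S_G (zero diagonal)."""
    d = 1.0 - sg
    np.fill_diagonal(d.values, 0.0)
    return d


def bionj(dm: pd.DataFrame, clamp_negative: bool = True) -> dendropy.Tree:
    """Build an unrooted BIONJ tree from a symmetric distance matrix.

    Negative branch-length estimates are clamped to zero with the deficit
    transferred to the sibling branch. Ties in the Q-criterion are broken by
    the lowest (i, j) index pair in current matrix order.
    """
    ids = list(dm.index)
    n = len(ids)
    taxa = dendropy.TaxonNamespace(ids)
    tree = dendropy.Tree(taxon_namespace=taxa)
    if n == 1:
        tree.seed_node.taxon = taxa.get_taxon(ids[0])
        return tree
    nodes = []
    for name in ids:
        nd = dendropy.Node(taxon=taxa.get_taxon(name))
        nodes.append(nd)
    if n == 2:
        d = float(dm.iloc[0, 1])
        for nd in nodes:
            nd.edge.length = d / 2
            tree.seed_node.add_child(nd)
        return tree

    D = dm.values.astype(float).copy()
    V = D.copy()  # initial variances equal distances
    active = list(range(n))

    def _branches(i, j, m):
        r_i = D[i, active].sum()
        r_j = D[j, active].sum()
        bi = 0.5 * D[i, j] + (r_i - r_j) / (2 * (m - 2))
        bj = D[i, j] - bi
        if clamp_negative:
            if bi < 0:
                bj += bi
                bi = 0.0
            if bj < 0:
                bi += bj
                bj = 0.0
            bi, bj = max(bi, 0.0), max(bj, 0.0)
        return bi, bj

    while len(active) > 3:
        m = len(active)
        r = {i: D[i, active].sum() for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-15:
                    best = (q, i, j)
        _, i, j = best
        bi, bj = _branches(i, j, m)
        new = dendropy.Node()
        nodes[i].edge.length = bi
        nodes[j].edge.length = bj
        new.add_child(nodes[i])
        new.add_child(nodes[j])

        # BIONJ variance-weighted reduction
        lam = 0.5
        vij = V[i, j]
        others = [k for k in active if k not in (i, j)]
        if vij > 1e-12 and others:
            lam = 0.5 + sum(V[j, k] - V[i, k] for k in others) / (2 * len(others) * vij)
            lam = min(1.0, max(0.0, lam))
        for k in others:
            D[i, k] = D[k, i] = lam * (D[i, k] - bi) + (1 - lam) * (D[j, k] - bj)
            V[i, k] = V[k, i] = lam * V[i, k] + (1 - lam) * V[j, k] - lam * (1 - lam) * vij
        nodes[i] = new
        active.remove(j)

    # final 3-taxon star
    i, j, k = active
    bi = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    bj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    bk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    if clamp_negative:
        bi, bj, bk = (max(x, 0.0) for x in (bi, bj, bk))
    for idx, b in zip((i, j, k), (bi, bj, bk)):
        nodes[idx].edge.length = b
        tree.seed_node.add_child(nodes[idx])
    tree.is_rooted = False
    return tree


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root at the midpoint of the longest leaf-to-leaf path (in place)."""
    total = sum((e.length or 0.0) for e in tree.edges())
    n_leaves = sum(1 for _ in tree.leaf_node_iter())
    if total <= 0 or n_leaves <= 2:
        # zero-length or two-leaf trees: the BIONJ construction already
        # splits the single path evenly at the seed node
        tree.is_rooted = True
        return tree
    tree.reroot_at_midpoint(update_bipartitions=True)
    tree.is_rooted = True
    return tree


def tree_distance_matrix(tree: dendropy.Tree) -> pd.DataFrame:
    """Leaf-to-leaf path lengths on the tree (additivity oracle helper)."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    mat = np.zeros((len(taxa), len(taxa)))
    for a in range(len(taxa)):
        for b in range(a + 1, len(taxa)):
            mat[a, b] = mat[b, a] = pdm.patristic_distance(taxa[a], taxa[b])
    return pd.DataFrame(mat, index=labels, columns=labels)


def to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def from_newick(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick")


def log_scaled_lengths(tree: dendropy.Tree, eps: float = 1e-3) -> dendropy.Tree:
    """Copy with log10(1 + d/eps) branch lengths, for display only."""
    disp = tree.clone(depth=1)
    for e in disp.edges():
        if e.length is not None:
            e.length = float(np.log10(1.0 + e.length / eps))
    return disp
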