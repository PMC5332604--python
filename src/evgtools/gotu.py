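"""Genomic OTUs: average-linkage clustering at S_G cutoffs, genus-level
cutoff selection by adjusted Rand index, and richness estimation.

Clustering agglomerates on distance 1 - S_G with average linkage (UPGMA-
style) and cuts the dendrogram at 1 - cutoff, so members of a cluster have
average inter-member similarity at least the cutoff. The genus-level cutoff
is chosen by scanning a 0.01-step grid and maximizing the adjusted Rand
index against a reference genus labelling. Richness uses the bias-corrected
Chao1 estimator and analytic (hypergeometric) rarefaction with bootstrap
confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, exp

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, fcluster
from scipy.spatial.distance import squareform
from scipy.special import gammaln


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _linkage_from_sg(sg: pd.DataFrame):
    d = 1.0 - sg.values.astype(float)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2, 0.0, None)  # enforce exact symmetry
    return linkage(squareform(d, checks=False), method="average")


def average_linkage_cluster(sg: pd.DataFrame, cutoff: float) -> dict[str, int]:
    """Partition of the genomes at an S_G cutoff (cluster ids are arbitrary)."""
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must be in (0, 1)")
    Z = _linkage_from_sg(sg)
    labels = fcluster(Z, t=1.0 - cutoff, criterion="distance")
    return dict(zip(sg.index, (int(x) for x in labels)))


# ---------------------------------------------------------------------------
# adjusted Rand index
# ---------------------------------------------------------------------------

def adjusted_rand_index(p1: dict[str, object], p2: dict[str, object]) -> float:
    """Chance-corrected agreement between two partitions of the same items."""
    if set(p1) != set(p2):
        raise ValueError("partitions cover different item sets")
    items = sorted(p1)
    n = len(items)
    if n < 2:
        raise ValueError("need at least two items")
    table: dict[tuple[object, object], int] = {}
    a: dict[object, int] = {}
    b: dict[object, int] = {}
    for it in items:
        c1, c2 = p1[it], p2[it]
        table[(c1, c2)] = table.get((c1, c2), 0) + 1
        a[c1] = a.get(c1, 0) + 1
        b[c2] = b.get(c2, 0) + 1
    sum_ij = sum(comb(v, 2) for v in table.values())
    sum_a = sum(comb(v, 2) for v in a.values())
    sum_b = sum(comb(v, 2) for v in b.values())
    expected = sum_a * sum_b / comb(n, 2)
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:  # both partitions trivial
        return 1.0
    return (sum_ij - expected) / (max_index - expected)


@dataclass
class CutoffEvaluation:
    cutoffs: np.ndarray
    ari: np.ndarray
    best_cutoff: float
    best_ari: float
    best_partition: dict[str, int]


def scan_cutoffs(
    sg: pd.DataFrame,
    truth_labels: dict[str, object],
    grid_step: float = 0.01,
    grid: np.ndarray | None = None,
) -> CutoffEvaluation:
    """ARI against reference labels over a cutoff grid; argmax reported.

    Only the labelled genome subset enters the ARI; ties are resolved toward
    the smallest cutoff.
    """
    labeled = [g for g in sg.index if g in truth_labels]
    if len(set(truth_labels[g] for g in labeled)) < 2:
        raise ValueError("need at least two labelled genera")
    if grid is None:
        grid = np.arange(grid_step, 1.0, grid_step)
    sub = sg.loc[labeled, labeled]
    Z = _linkage_from_sg(sub)
    truth = {g: truth_labels[g] for g in labeled}
    aris = np.empty(len(grid))
    parts = []
    for gi, cut in enumerate(grid):
        labels = fcluster(Z, t=1.0 - cut, criterion="distance")
        part = dict(zip(labeled, (int(x) for x in labels)))
        parts.append(part)
        aris[gi] = adjusted_rand_index(part, truth)
    best_idx = int(np.argmax(aris))  # argmax keeps the first (smallest) cutoff
    return CutoffEvaluation(
        cutoffs=np.asarray(grid), ari=aris,
        best_cutoff=float(grid[best_idx]), best_ari=float(aris[best_idx]),
        best_partition=parts[best_idx],
    )


# ---------------------------------------------------------------------------
# richness
# ---------------------------------------------------------------------------

def cluster_sizes(partition: dict[str, object]) -> list[int]:
    sizes: dict[object, int] = {}
    for c in partition.values():
        sizes[c] = sizes.get(c, 0) + 1
    return sorted(sizes.values(), reverse=True)


def chao1(sizes: list[int], bias_corrected: bool = True) -> float:
    """Chao1 richness from cluster sizes (singletons f1, doubletons f2)."""
    sizes = [s for s in sizes if s > 0]
    s_obs = len(sizes)
    f1 = sum(1 for s in sizes if s == 1)
    f2 = sum(1 for s in sizes if s == 2)
    if bias_corrected or f2 == 0:
        return s_obs + f1 * (f1 - 1) / (2 * (f2 + 1))
    return s_obs + f1 * f1 / (2 * f2)


def _log_comb(n: np.ndarray | int, k: np.ndarray | int):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def expected_richness(sizes: list[int], m: int) -> float:
    """Analytic rarefaction: expected clusters in a sample of m genomes,
    E[S_m] = sum_k [1 - C(n - n_k, m) / C(n, m)]."""
    n = sum(sizes)
    if not 0 <= m <= n:
        raise ValueError("subsample size out of range")
    if m == 0:
        return 0.0
    total = 0.0
    for nk in sizes:
        if n - nk < m:
            total += 1.0
        else:
            total += 1.0 - exp(float(_log_comb(n - nk, m) - _log_comb(n, m)))
    return total


@dataclass
class RarefactionCurve:
    depths: np.ndarray
    expected: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    s_obs: int
    chao1: float


def rarefaction(
    partition: dict[str, object],
    n_boot: int = 100,
    ci: float = 0.95,
    depths: np.ndarray | None = None,
    seed: int = 0,
) -> RarefactionCurve:
    """Rarefaction curve with percentile bootstrap confidence intervals.

    Bootstrap replicates resample genomes with replacement and recompute the
    analytic curve on the resampled cluster sizes.
    """
    genomes = sorted(partition)
    n = len(genomes)
    if n < 1:
        raise ValueError("empty partition")
    sizes = cluster_sizes(partition)
    if depths is None:
        depths = np.unique(np.linspace(1, n, min(n, 50)).astype(int))
    exp_curve = np.array([expected_richness(sizes, int(m)) for m in depths])

    rng = np.random.default_rng(seed)
    labels = np.array([partition[g] for g in genomes], dtype=object)
    boots = np.empty((n_boot, len(depths)))
    for b in range(n_boot):
        resampled = labels[rng.integers(0, n, size=n)]
        counts: dict[object, int] = {}
        for lb in resampled:
            counts[lb] = counts.get(lb, 0) + 1
        bsizes = sorted(counts.values(), reverse=True)
        boots[b] = [expected_richness(bsizes, int(m)) for m in depths]
    alpha = (1.0 - ci) / 2
    lo = np.quantile(boots, alpha, axis=0)
    hi = np.quantile(boots, 1 - alpha, axis=0)
    return RarefactionCurve(
        depths=depths, expected=exp_curve, ci_low=lo, ci_high=hi,
        s_obs=len(sizes), chao1=chao1(sizes),
    )


# ---------------------------------------------------------------------------
# cluster composition by source
# ---------------------------------------------------------------------------

def composition(
    partition: dict[str, object], source_labels: dict[str, str]
) -> pd.DataFrame:
    """Shares of single-source and shared clusters.

    Clusters are categorized by the set of member source labels (e.g.
    environmental-only, reference-only, shared); shares are reported both by
    cluster count and by genome count and each sum to 1.
    """
    missing = [g for g in partition if g not in source_labels]
    if missing:
        raise ValueError(f"unlabelled genomes: {missing[:3]}...")
    members: dict[object, list[str]] = {}
    for g, c in partition.items():
        members.setdefault(c, []).append(g)
    cat_clusters: dict[str, int] = {}
    cat_genomes: dict[str, int] = {}
    for mems in members.values():
        srcs = sorted({source_labels[g] for g in mems})
        cat = srcs[0] if len(srcs) == 1 else "shared"
        cat_clusters[cat] = cat_clusters.get(cat, 0) + 1
        cat_genomes[cat] = cat_genomes.get(cat, 0) + len(mems)
    cats = sorted(set(cat_clusters) | set(cat_genomes))
    n_clust = sum(cat_clusters.values())
    n_gen = sum(cat_genomes.values())
    return pd.DataFrame(
        {
            "category": cats,
            "clusters": [cat_clusters.get(c, 0) for c in cats],
            "share_by_cluster": [cat_clusters.get(c, 0) / n_clust for c in cats],
            "genomes": [cat_genomes.get(c, 0) for c in cats],
            "share_by_genome": [cat_genomes.get(c, 0) / n_gen for c in cats],
        }
    )
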