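"""FPKM abundance tables and sequence recruitment.

FPKM = fragments / (genome length in kb x library size in millions of
fragments), with each fragment assigned to its single best-scoring genome
(ties split equally). gOTU abundances sum member FPKMs per sample, first
collapsing declared sample groups (e.g. replicate samples from one site) to
their mean, then averaging across the resulting samples; normalized
abundances are scaled to sum to 100. Recruitment applies the two-stage
filter: expect value below threshold, then >= 60% identity and >= 80% query
coverage.
"""

from __future__ import annotations

import pandas as pd

from .similarity import HSP


def assign_fragments(hits: pd.DataFrame) -> pd.DataFrame:
    """Fragment counts per genome from best-scoring assignments.

    ``hits`` columns: fragment_id, genome_id, sample, score. Each fragment
    (within a sample) contributes 1 to its best-scoring genome; exact score
    ties are split equally.
    """
    rows = []
    for (sample, _frag), grp in hits.groupby(["sample", "fragment_id"], sort=False):
        top = grp[grp["score"] == grp["score"].max()]
        w = 1.0 / len(top)
        for gid in top["genome_id"]:
            rows.append({"sample": sample, "genome_id": gid, "count": w})
    if not rows:
        return pd.DataFrame(columns=["genome_id", "sample", "count"])
    df = pd.DataFrame(rows)
    return df.groupby(["genome_id", "sample"], sort=False)["count"].sum().reset_index()


def fpkm(
    fragment_counts: pd.DataFrame,
    genome_lengths: dict[str, int],
    library_sizes: dict[str, float],
) -> pd.DataFrame:
    """Genome x sample FPKM table.

    ``fragment_counts`` columns: genome_id, sample, count. Library sizes are
    total mapped fragments per sample and must be positive.
    """
    for s, v in library_sizes.items():
        if v <= 0:
            raise ValueError(f"non-positive library size for sample {s!r}")
    samples = list(library_sizes)
    genomes = list(genome_lengths)
    table = pd.DataFrame(0.0, index=genomes, columns=samples)
    for r in fragment_counts.itertuples():
        table.loc[r.genome_id, r.sample] += r.count
    for g in genomes:
        if genome_lengths[g] <= 0:
            raise ValueError(f"non-positive length for genome {g!r}")
        table.loc[g] /= genome_lengths[g] / 1000.0
    for s in samples:
        table[s] /= library_sizes[s] / 1_000_000.0
    return table


def gotu_fpkm(
    fpkm_table: pd.DataFrame,
    partition: dict[str, object],
    sample_groups: dict[str, list[str]] | None = None,
) -> pd.Series:
    """Per-gOTU FPKM: sum member genomes per sample, average over samples.

    Samples listed in a group are first averaged into one pseudo-sample so a
    deeply replicated site does not dominate the cross-sample mean.
    """
    missing = [g for g in fpkm_table.index if g not in partition]
    if missing:
        raise ValueError(f"genomes missing from partition: {missing[:3]}")
    table = fpkm_table.copy()
    if sample_groups:
        for gname, members in sample_groups.items():
            present = [m for m in members if m in table.columns]
            if not present:
                continue
            pseudo = table[present].mean(axis=1)
            table = table.drop(columns=present)
            table[gname] = pseudo
    sums = table.groupby(pd.Series({g: partition[g] for g in table.index})).sum()
    return sums.mean(axis=1)


def normalize_abundance(gotu_values: pd.Series) -> pd.Series:
    """Normalized FPKM in percent; the column sums to 100."""
    total = gotu_values.sum()
    if total <= 0:
        raise ValueError("all abundances are zero")
    return 100.0 * gotu_values / total


def recruit(
    hits: list[HSP],
    query_lengths: dict[str, int],
    target_sets: dict[str, set[str]],
    min_identity: float = 0.60,
    min_query_cov: float = 0.80,
    expect_max: float = 1e-3,
) -> pd.DataFrame:
    """Fraction of queries recruited to each target set.

    A query is recruited when at least one hit to a member of the set passes
    the expect threshold and then the identity and query-coverage filters
    (coverage = aligned query span / query length).
    """
    if not query_lengths:
        raise ValueError("no queries")
    passing: dict[str, set[str]] = {q: set() for q in query_lengths}
    for h in hits:
        if h.evalue >= expect_max or h.identity < min_identity:
            continue
        a, b = h.query_span
        if (b - a + 1) / query_lengths[h.query] < min_query_cov:
            continue
        passing.setdefault(h.query, set()).add(h.subject)
    rows = []
    n = len(query_lengths)
    for name, targets in target_sets.items():
        recruited = sum(1 for q in query_lengths if passing.get(q) and passing[q] & targets)
        rows.append({"target_set": name, "recruited": recruited,
                     "total": n, "fraction": recruited / n})
    return pd.DataFrame(rows)
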