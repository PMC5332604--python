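"""Complete-genome identification and dereplication of assembled contigs.

A contig is called circular (complete) when its 5' and 3' terminal regions
are nearly identical: overlap of at least 50 bp at strictly more than 94%
identity. Genomes are kept when longer than 10 kb. Pairs of genomes are
redundant when merged nucleotide HSPs cover at least 80% of the shorter
genome at a mean identity of at least 95%; single-linkage clustering of
redundant pairs yields the nonredundant set.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd

from .similarity import HSP


@dataclass(frozen=True)
class CircularityCall:
    contig_id: str
    evaluable: bool
    overlap_length: int
    overlap_identity: float
    is_circular: bool
    trimmed_length: int


@dataclass(frozen=True)
class RedundancyPair:
    id_a: str
    id_b: str
    coverage_of_shorter: float
    mean_identity: float
    redundant: bool


def detect_circular(
    contig_id: str,
    sequence: str,
    min_overlap: int = 50,
    min_identity: float = 0.94,
    seed_k: int = 15,
    max_window: int | None = None,
) -> CircularityCall:
    """Find a terminal direct repeat marking an assembled circular genome.

    Candidate suffix-prefix overlaps are seeded by exact matches of k-mers
    from the start of the contig within a bounded window at the 3' end, then
    evaluated ungapped over the full implied overlap. The call is circular
    iff the best overlap is >= ``min_overlap`` bp at identity strictly above
    ``min_identity``; the duplicated terminus is trimmed from
    ``trimmed_length``.
    """
    seq = sequence.upper()
    n = len(seq)
    if n <= 2 * min_overlap:
        return CircularityCall(contig_id, False, 0, 0.0, False, n)
    window = max_window if max_window is not None else min(5000, int(0.2 * n))
    window = min(max(window, min_overlap + seed_k), n - 1)
    tail_start = n - window
    tail = seq[tail_start:]

    candidates: set[int] = set()
    for off in range(min(5, n - seed_k)):  # seeds from the first few positions
        kmer = seq[off : off + seed_k]
        pos = tail.find(kmer)
        while pos != -1:
            overlap = n - (tail_start + pos - off)
            if min_overlap <= overlap <= window:
                candidates.add(overlap)
            pos = tail.find(kmer, pos + 1)

    best = (0, 0.0)  # (overlap, identity)
    for o in sorted(candidates, reverse=True):
        a, b = seq[:o], seq[-o:]
        ident = sum(x == y for x, y in zip(a, b)) / o
        if ident > min_identity and o > best[0]:
            best = (o, ident)
        elif best[0] == 0 and ident > best[1]:
            best = (0, ident)
    o, ident = best
    circular = o >= min_overlap and ident > min_identity
    return CircularityCall(
        contig_id, True, o if circular else 0, ident, circular, n - o if circular else n
    )


def trim_terminal_repeat(sequence: str, call: CircularityCall) -> str:
    return sequence[: call.trimmed_length]


def filter_by_length(contigs: dict[str, str], min_bp: int = 10_000) -> dict[str, str]:
    """Keep contigs strictly larger than ``min_bp``."""
    return {cid: s for cid, s in contigs.items() if len(s) > min_bp}


def gc_fraction(sequence: str) -> float:
    """G+C over unambiguous bases; NaN when no unambiguous base exists."""
    seq = sequence.upper()
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return float("nan")
    return (seq.count("G") + seq.count("C")) / acgt


def genome_stats(genomes: dict[str, str]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "genome_id": list(genomes),
            "length": [len(s) for s in genomes.values()],
            "gc_fraction": [gc_fraction(s) for s in genomes.values()],
        }
    )


# ---------------------------------------------------------------------------
# redundancy
# ---------------------------------------------------------------------------

def _union_length(intervals: list[tuple[int, int]]) -> int:
    total, cur_a, cur_b = 0, None, None
    for a, b in sorted(intervals):
        if cur_b is None or a > cur_b:
            if cur_b is not None:
                total += cur_b - cur_a + 1
            cur_a, cur_b = a, b
        else:
            cur_b = max(cur_b, b)
    if cur_b is not None:
        total += cur_b - cur_a + 1
    return total


def evaluate_pair(
    id_a: str,
    id_b: str,
    len_a: int,
    len_b: int,
    hsps: list[HSP],
    min_coverage: float = 0.80,
    min_identity: float = 0.95,
) -> RedundancyPair:
    """Apply the merged-HSP coverage and mean-identity redundancy rule.

    HSPs are projected onto the shorter genome; coverage uses the interval
    union (overlaps counted once) while mean identity is the alignment-
    length-weighted mean over all HSPs.
    """
    shorter, shorter_len = (id_a, len_a) if len_a <= len_b else (id_b, len_b)
    intervals: list[tuple[int, int]] = []
    wsum = lsum = 0.0
    for h in hsps:
        if h.query == shorter:
            a, b = sorted((h.qstart, h.qend))
        elif h.subject == shorter:
            a, b = sorted((h.sstart, h.send))
        else:
            continue
        intervals.append((a, b))
        wsum += h.identity * h.length
        lsum += h.length
    if not intervals:
        return RedundancyPair(id_a, id_b, 0.0, 0.0, False)
    coverage = _union_length(intervals) / shorter_len
    mean_ident = wsum / lsum
    redundant = coverage >= min_coverage and mean_ident >= min_identity
    return RedundancyPair(id_a, id_b, coverage, mean_ident, redundant)


def find_redundant_pairs(
    genomes: dict[str, str],
    hsps: list[HSP],
    min_coverage: float = 0.80,
    min_identity: float = 0.95,
) -> list[RedundancyPair]:
    """Evaluate the redundancy rule for every genome pair with alignments."""
    by_pair: dict[tuple[str, str], list[HSP]] = {}
    for h in hsps:
        if h.query == h.subject:
            continue
        key = tuple(sorted((h.query, h.subject)))
        by_pair.setdefault(key, []).append(h)
    out = []
    for a, b in combinations(sorted(genomes), 2):
        pair_hsps = by_pair.get((a, b), [])
        out.append(
            evaluate_pair(a, b, len(genomes[a]), len(genomes[b]), pair_hsps,
                          min_coverage, min_identity)
        )
    return out


def dereplicate(
    genomes: dict[str, str], pairs: list[RedundancyPair]
) -> tuple[dict[str, str], dict[str, str]]:
    """Single-linkage clustering of redundant pairs; one representative per
    component (longest genome, ties by lexicographic id).

    Returns (nonredundant genomes, member -> representative mapping).
    """
    parent = {g: g for g in genomes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for p in pairs:
        if p.redundant:
            ra, rb = find(p.id_a), find(p.id_b)
            if ra != rb:
                parent[rb] = ra

    components: dict[str, list[str]] = {}
    for g in genomes:
        components.setdefault(find(g), []).append(g)
    rep_of: dict[str, str] = {}
    nonredundant: dict[str, str] = {}
    for members in components.values():
        rep = min(members, key=lambda g: (-len(genomes[g]), g))
        nonredundant[rep] = genomes[rep]
        for m in members:
            rep_of[m] = rep
    return nonredundant, rep_of
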