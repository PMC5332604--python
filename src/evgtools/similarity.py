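"""Genome-wide translated-alignment similarity (S_G).

S_G is a normalized genome-to-genome score derived from translated (tBLASTx)
local alignments. For a pair (A, B) the HSPs of each search direction are
reduced to a tiling score: HSPs are taken greedily by descending bit score,
discarding any HSP whose query interval overlaps an already selected HSP by
more than half of its own query span; the selected bit scores are summed and
the two directions averaged. S_G = raw(A,B) / min(raw(A,A), raw(B,B)),
clipped to [0, 1], so identical genomes score exactly 1 and pairs with no
detectable similarity score 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .orfs import revcomp, translate


@dataclass(frozen=True)
class HSP:
    """A scored local alignment segment (1-based inclusive coordinates).

    ``identity`` is a fraction in [0, 1]; in translated mode ``length`` is in
    residues while coordinates remain nucleotide positions.
    """

    query: str
    subject: str
    identity: float
    length: int
    mismatches: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    @property
    def query_span(self) -> tuple[int, int]:
        return (self.qstart, self.qend) if self.qstart <= self.qend else (self.qend, self.qstart)


# ---------------------------------------------------------------------------
# 12-column tabular I/O (BLAST outfmt 6)
# ---------------------------------------------------------------------------

def parse_tabular_line(line: str) -> HSP:
    f = line.rstrip("\n").split("\t")
    return HSP(
        query=f[0], subject=f[1], identity=float(f[2]) / 100.0, length=int(f[3]),
        mismatches=int(f[4]), gapopen=int(f[5]), qstart=int(f[6]), qend=int(f[7]),
        sstart=int(f[8]), send=int(f[9]), evalue=float(f[10]), bitscore=float(f[11]),
    )


def read_tabular(path) -> list[HSP]:
    hsps = []
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                hsps.append(parse_tabular_line(line))
    return hsps


def write_tabular(hsps: list[HSP], path) -> None:
    with open(path, "w") as fh:
        for h in hsps:
            fh.write(
                f"{h.query}\t{h.subject}\t{h.identity * 100:.3f}\t{h.length}\t"
                f"{h.mismatches}\t{h.gapopen}\t{h.qstart}\t{h.qend}\t{h.sstart}\t"
                f"{h.send}\t{h.evalue:.2g}\t{h.bitscore:.1f}\n"
            )


# ---------------------------------------------------------------------------
# translation and scoring arithmetic
# ---------------------------------------------------------------------------

def six_frame_translate(sequence: str) -> list[str]:
    """Peptides for frames +1, +2, +3, -1, -2, -3 (stops rendered as ``*``)."""
    fwd = sequence.upper()
    rev = revcomp(fwd)
    return [translate(fwd[i:]) for i in range(3)] + [translate(rev[i:]) for i in range(3)]


def bitscore_from_raw(raw: float, lambda_: float = 0.3176, K: float = 0.134) -> float:
    """Karlin-Altschul normalized bit score, (lambda*raw - ln K) / ln 2.

    Defaults are the ungapped BLOSUM62 parameters; pass lambda_=0.267,
    K=0.041 for gapped statistics.
    """
    return (lambda_ * raw - math.log(K)) / math.log(2)


# ---------------------------------------------------------------------------
# HSP search (delegates to BLAST+)
# ---------------------------------------------------------------------------

def find_hsps(
    queries: dict[str, str],
    subjects: dict[str, str],
    mode: str = "translated",
    evalue: float = 1e-3,
) -> list[HSP]:
    """Local alignments between all queries and all subjects.

    ``mode`` selects translated (tBLASTx), nucleotide (BLASTn) or protein
    (BLASTp) comparison.
    """
    from . import blast

    for name, s in {**queries, **subjects}.items():
        if not s:
            raise ValueError(f"empty sequence {name!r}")
    return blast.run_search(queries, subjects, mode=mode, evalue=evalue)


# ---------------------------------------------------------------------------
# S_G
# ---------------------------------------------------------------------------

def tile_score(hsps: list[HSP], max_overlap_fraction: float = 0.5) -> float:
    """Greedy one-direction tiling score: sum of selected bit scores.

    HSPs are visited by descending bit score (ties by query start, subject
    start, subject id); an HSP is discarded when its query interval overlaps
    any already selected HSP by more than ``max_overlap_fraction`` of its own
    span.
    """
    chosen: list[tuple[int, int]] = []
    total = 0.0
    for h in sorted(hsps, key=lambda h: (-h.bitscore, h.qstart, h.sstart, h.subject)):
        a, b = h.query_span
        span = b - a + 1
        if any(min(b, d) - max(a, c) + 1 > max_overlap_fraction * span for c, d in chosen):
            continue
        chosen.append((a, b))
        total += h.bitscore
    return total


def raw_similarity(hsps_ab: list[HSP], hsps_ba: list[HSP]) -> float:
    """Mean of the two directional tiling scores."""
    return 0.5 * (tile_score(hsps_ab) + tile_score(hsps_ba))


def compute_sg(raw_ab: float, raw_aa: float, raw_bb: float,
               normalization: str = "min") -> float:
    """Normalize a raw pair score by the self-scores, clipped to [0, 1]."""
    if raw_aa <= 0 or raw_bb <= 0:
        raise ValueError("self-scores must be positive")
    if normalization == "min":
        denom = min(raw_aa, raw_bb)
    elif normalization == "geometric":
        denom = math.sqrt(raw_aa * raw_bb)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return float(min(1.0, max(0.0, raw_ab / denom)))


def _candidate_pairs_by_kmer(
    genomes: dict[str, str], k: int = 18, min_shared: int = 2
) -> set[tuple[str, str]]:
    """Pairs sharing >= ``min_shared`` exact nucleotide k-mers.

    At genus-level divergence many k-mers survive in both genomes, while
    unrelated genomes essentially never share an 18-mer; this is a recall-
    oriented prefilter, not a similarity measure.
    """
    ids = list(genomes)
    index: dict[str, set[int]] = {}
    for gi, gid in enumerate(ids):
        seq = genomes[gid]
        seen = {seq[i : i + k] for i in range(0, len(seq) - k + 1)}
        for kmer in seen:
            index.setdefault(kmer, set()).add(gi)
    counts: dict[tuple[int, int], int] = {}
    for members in index.values():
        if 1 < len(members) <= 50:
            mem = sorted(members)
            for i, j in combinations(mem, 2):
                counts[(i, j)] = counts.get((i, j), 0) + 1
    return {
        (ids[i], ids[j]) for (i, j), c in counts.items() if c >= min_shared
    }


def sg_matrix(
    genomes: dict[str, str],
    mode: str = "translated",
    evalue: float = 1e-3,
    candidates: str | set[tuple[str, str]] = "all",
    normalization: str = "min",
) -> pd.DataFrame:
    """All-against-all S_G matrix (symmetric, unit diagonal).

    ``candidates='all'`` scores every pair in one search of all genomes
    against a database of all genomes. ``candidates='auto'`` restricts the
    search to pairs sharing exact nucleotide 18-mers (grouped into connected
    components); pairs outside the candidate set are assigned S_G = 0. An
    explicit set of id pairs may also be given.
    """
    ids = list(genomes)
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate genome ids")
    if len(ids) < 2:
        raise ValueError("need at least two genomes")

    if candidates == "all":
        pair_set = {tuple(sorted(p)) for p in combinations(ids, 2)}
    elif candidates == "auto":
        pair_set = _candidate_pairs_by_kmer(genomes)
    else:
        pair_set = {tuple(sorted(p)) for p in candidates}

    # connected components of the candidate graph; BLAST runs per component
    parent = {g: g for g in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in pair_set:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
    components: dict[str, list[str]] = {}
    for g in ids:
        components.setdefault(find(g), []).append(g)

    sg = pd.DataFrame(0.0, index=ids, columns=ids)
    np.fill_diagonal(sg.values, 1.0)
    for members in components.values():
        if len(members) < 2:
            continue
        sub = {g: genomes[g] for g in members}
        hsps = find_hsps(sub, sub, mode=mode, evalue=evalue)
        by_pair: dict[tuple[str, str], list[HSP]] = {}
        for h in hsps:
            by_pair.setdefault((h.query, h.subject), []).append(h)
        self_raw = {g: tile_score(by_pair.get((g, g), [])) for g in members}
        for a, b in combinations(members, 2):
            if tuple(sorted((a, b))) not in pair_set:
                continue
            raw_ab = raw_similarity(by_pair.get((a, b), []), by_pair.get((b, a), []))
            if self_raw[a] <= 0 or self_raw[b] <= 0:
                warnings.warn(f"zero self-score for {a if self_raw[a] <= 0 else b}")
                continue
            val = compute_sg(raw_ab, self_raw[a], self_raw[b], normalization)
            sg.loc[a, b] = sg.loc[b, a] = val
    return sg


def sg_from_hsp_table(
    hsps: list[HSP], ids: list[str], normalization: str = "min"
) -> pd.DataFrame:
    """S_G matrix from a precomputed (e.g. imported tabular) HSP set.

    The set must contain self-comparisons for every genome.
    """
    by_pair: dict[tuple[str, str], list[HSP]] = {}
    for h in hsps:
        by_pair.setdefault((h.query, h.subject), []).append(h)
    self_raw = {g: tile_score(by_pair.get((g, g), [])) for g in ids}
    sg = pd.DataFrame(0.0, index=ids, columns=ids)
    np.fill_diagonal(sg.values, 1.0)
    for a, b in combinations(ids, 2):
        if self_raw[a] <= 0 or self_raw[b] <= 0:
            raise ValueError(f"missing or zero self-score for {a!r} or {b!r}")
        raw_ab = raw_similarity(by_pair.get((a, b), []), by_pair.get((b, a), []))
        val = compute_sg(raw_ab, self_raw[a], self_raw[b], normalization)
        sg.loc[a, b] = sg.loc[b, a] = val
    return sg
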