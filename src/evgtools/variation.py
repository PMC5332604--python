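"""Intra-population variation: SNP calling and nucleotide diversity.

Pileups count only high-quality aligned bases (Phred > 30). SNPs are
evaluated at positions with >= 5x high-quality coverage by six criteria
applied to the second-most-frequent nucleotide: (i) at least one read,
(ii) at least two reads, (iii) more than 10% of coverage, (iv) more than
20% of coverage, (v) iii or ii, (vi) iii and ii. Nucleotide diversity is
the mean over evaluable sites of the sample-size-corrected per-site
heterozygosity pi_site = (C/(C-1)) (1 - sum_b (c_b/C)^2), reported in %.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

BASE_ORDER = "ACGT"
CRITERIA = ("i", "ii", "iii", "iv", "v", "vi")


@dataclass(frozen=True)
class PileupColumn:
    genome_id: str
    position: int  # 1-based
    counts: tuple[int, int, int, int]  # A, C, G, T high-quality counts

    @property
    def coverage(self) -> int:
        return sum(self.counts)


@dataclass(frozen=True)
class SNPCall:
    genome_id: str
    position: int
    coverage: int
    second_allele: str
    second_allele_count: int
    verdicts: dict[str, bool]


# ---------------------------------------------------------------------------
# pileup construction
# ---------------------------------------------------------------------------

def build_pileup_from_sam(path, q_threshold: int = 30) -> list[PileupColumn]:
    """Per-position high-quality base counts from a SAM/BAM file.

    Bases aligned with quality <= ``q_threshold`` are excluded. Indel and
    clipped positions are skipped via the aligned-pairs interface.
    """
    import pysam

    counts: dict[str, np.ndarray] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        lengths = dict(zip(af.references, af.lengths))
        for read in af:
            if read.is_unmapped or read.query_sequence is None:
                continue
            ref = read.reference_name
            arr = counts.setdefault(ref, np.zeros((lengths[ref], 4), dtype=np.int64))
            quals = read.query_qualities
            seq = read.query_sequence
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                if quals is not None and quals[qpos] <= q_threshold:
                    continue
                b = BASE_ORDER.find(seq[qpos])
                if b >= 0:
                    arr[rpos, b] += 1
    return _columns_from_arrays(counts)


def build_pileup_from_sim(simreads, q_threshold: int = 30) -> list[PileupColumn]:
    """Pileup from the simulator's true placements (no mapper involved)."""
    counts: dict[str, np.ndarray] = {}
    by_id = {rid: (f, fq, r, rq) for rid, f, fq, r, rq in simreads.pairs}
    from .orfs import revcomp

    for aln in simreads.alignments:
        L = simreads.genome_lengths[aln.genome_id]
        arr = counts.setdefault(aln.genome_id, np.zeros((L, 4), dtype=np.int64))
        f, fq, r, rq = by_id[aln.read_id]
        for seq, quals, start in ((f, fq, aln.fwd_start), (revcomp(r), list(reversed(rq)), aln.rev_start)):
            for i, (base, q) in enumerate(zip(seq, quals)):
                if q <= q_threshold:
                    continue
                b = BASE_ORDER.find(base)
                if b >= 0:
                    arr[(start + i) % L, b] += 1
    return _columns_from_arrays(counts)


def read_pileup_tsv(path) -> list[PileupColumn]:
    df = pd.read_csv(path, sep="\t")
    return [
        PileupColumn(r.genome_id, int(r.position), (int(r.A), int(r.C), int(r.G), int(r.T)))
        for r in df.itertuples()
    ]


def write_pileup_tsv(columns: Iterable[PileupColumn], path) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\tposition\tA\tC\tG\tT\n")
        for c in columns:
            fh.write(f"{c.genome_id}\t{c.position}\t" + "\t".join(map(str, c.counts)) + "\n")


def _columns_from_arrays(counts: dict[str, np.ndarray]) -> list[PileupColumn]:
    out = []
    for gid in counts:
        arr = counts[gid]
        covered = np.flatnonzero(arr.sum(axis=1) > 0)
        for pos in covered:
            out.append(PileupColumn(gid, int(pos) + 1, tuple(int(x) for x in arr[pos])))
    return out


# ---------------------------------------------------------------------------
# SNP criteria
# ---------------------------------------------------------------------------

def call_snps(column: PileupColumn, min_coverage: int = 5) -> SNPCall | None:
    """Six-criteria verdicts for one pileup column; None below 5x coverage.

    The second-most-frequent base is found with ties broken in fixed
    A < C < G < T order; "more than" thresholds are strict.
    """
    cov = column.coverage
    if cov < min_coverage:
        return None
    order = sorted(range(4), key=lambda b: (-column.counts[b], b))
    second = order[1]
    n2 = column.counts[second]
    crit_i = n2 >= 1
    crit_ii = n2 >= 2
    crit_iii = n2 > 0.10 * cov
    crit_iv = n2 > 0.20 * cov
    verdicts = {
        "i": crit_i,
        "ii": crit_ii,
        "iii": crit_iii,
        "iv": crit_iv,
        "v": crit_iii or crit_ii,
        "vi": crit_iii and crit_ii,
    }
    return SNPCall(column.genome_id, column.position, cov, BASE_ORDER[second], n2, verdicts)


def snp_rate(calls: list[SNPCall], evaluable_sites: int) -> dict[str, float]:
    """Percentage of evaluable sites positive under each criterion."""
    if evaluable_sites <= 0:
        raise ValueError("no evaluable sites")
    rates = {}
    for crit in CRITERIA:
        positives = sum(1 for c in calls if c.verdicts[crit])
        rates[crit] = 100.0 * positives / evaluable_sites
    return rates


# ---------------------------------------------------------------------------
# nucleotide diversity
# ---------------------------------------------------------------------------

def site_diversity(counts, min_coverage: int = 5) -> float | None:
    """Unbiased per-site heterozygosity, or None when not evaluable."""
    cov = sum(counts)
    if cov < min_coverage:
        return None
    sq = sum((c / cov) ** 2 for c in counts)
    return cov / (cov - 1) * (1.0 - sq)


def nucleotide_diversity(columns: Iterable[PileupColumn], min_coverage: int = 5) -> float:
    """Genome-level pi: mean site diversity over evaluable sites, in %."""
    vals = [v for c in columns if (v := site_diversity(c.counts, min_coverage)) is not None]
    if not vals:
        raise ValueError("no evaluable sites")
    return 100.0 * float(np.mean(vals))


def diversity_report(
    columns: list[PileupColumn], min_coverage: int = 5
) -> pd.DataFrame:
    """Per-genome SNP rates (all six criteria) and nucleotide diversity."""
    by_genome: dict[str, list[PileupColumn]] = {}
    for c in columns:
        by_genome.setdefault(c.genome_id, []).append(c)
    rows = []
    for gid, cols in by_genome.items():
        calls = [s for c in cols if (s := call_snps(c, min_coverage)) is not None]
        n_eval = sum(1 for c in cols if c.coverage >= min_coverage)
        if n_eval == 0:
            continue
        rates = snp_rate(calls, n_eval)
        row = {"genome_id": gid, "evaluable_sites": n_eval,
               "pi_percent": nucleotide_diversity(cols, min_coverage)}
        row.update({f"snp_rate_{k}": v for k, v in rates.items()})
        rows.append(row)
    return pd.DataFrame(rows)
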