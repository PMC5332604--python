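"""Four-step quality control of paired-end reads.

The procedure, applied in fixed order: (i) exact duplicate pairs are removed;
(ii) overlapping mates are merged and both merged and unmerged reads are
kept; (iii) reads are removed when fewer than 80% of positions have Phred
quality above 30; (iv) reads are removed when ambiguous bases plus
DUST-masked low-complexity regions exceed 40% of the length. When one mate
of a pair is removed in step (iii) or (iv), the other mate is retained as a
single read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .orfs import revcomp


@dataclass(frozen=True)
class ReadPair:
    id: str
    fwd_seq: str
    fwd_qual: tuple[int, ...]
    rev_seq: str
    rev_qual: tuple[int, ...]

    def __post_init__(self):
        if len(self.fwd_seq) != len(self.fwd_qual) or len(self.rev_seq) != len(self.rev_qual):
            raise ValueError("sequence and quality lengths differ")


@dataclass(frozen=True)
class Read:
    id: str
    seq: str
    qual: tuple[int, ...]


@dataclass
class QCReport:
    input_pairs: int = 0
    duplicate_pairs_removed: int = 0
    pairs_merged: int = 0
    quality_failed: int = 0
    complexity_failed: int = 0
    kept_merged: int = 0
    kept_pairs: int = 0
    kept_singletons: int = 0

    def as_dict(self) -> dict:
        return self.__dict__.copy()


@dataclass
class QCResult:
    merged: list[Read] = field(default_factory=list)
    pairs: list[ReadPair] = field(default_factory=list)
    singletons: list[Read] = field(default_factory=list)
    report: QCReport = field(default_factory=QCReport)


# ---------------------------------------------------------------------------
# (i) deduplication
# ---------------------------------------------------------------------------

def deduplicate(pairs: list[ReadPair]) -> list[ReadPair]:
    """Remove exact duplicate pairs (both mates identical), order-stable.

    Qualities are ignored in the comparison; the first occurrence is kept.
    """
    seen: set[tuple[str, str]] = set()
    out = []
    for p in pairs:
        key = (p.fwd_seq, p.rev_seq)
        if key not in seen:
            seen.add(key)
            out.append(p)
    return out


# ---------------------------------------------------------------------------
# (ii) pair merging
# ---------------------------------------------------------------------------

def merge_pairs(
    pairs: list[ReadPair],
    min_overlap: int = 10,
    max_mismatch_density: float = 0.25,
) -> tuple[list[Read], list[ReadPair]]:
    """Merge mates whose best 3' overlap passes the density threshold.

    The forward read is compared against the reverse complement of the
    reverse read over every overlap length >= ``min_overlap``; the overlap
    with the lowest mismatch density (ties: longest) wins. Disagreeing
    positions are resolved in favour of the higher-quality base.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    merged, unmerged = [], []
    for p in pairs:
        rc = revcomp(p.rev_seq)
        rc_qual = tuple(reversed(p.rev_qual))
        best = None  # (density, -overlap, mismatches)
        max_o = min(len(p.fwd_seq), len(rc))
        for o in range(min_overlap, max_o + 1):
            a, b = p.fwd_seq[-o:], rc[:o]
            mism = sum(x != y for x, y in zip(a, b))
            dens = mism / o
            if dens <= max_mismatch_density and (best is None or (dens, -o) < best[:2]):
                best = (dens, -o, mism)
        if best is None:
            unmerged.append(p)
            continue
        o = -best[1]
        fseq, fq = list(p.fwd_seq), list(p.fwd_qual)
        for i in range(o):
            fi = len(fseq) - o + i
            if fseq[fi] == rc[i]:
                fq[fi] = max(fq[fi], rc_qual[i])
            elif rc_qual[i] > fq[fi]:
                fseq[fi], fq[fi] = rc[i], rc_qual[i]
        seq = "".join(fseq) + rc[o:]
        qual = tuple(fq) + rc_qual[o:]
        merged.append(Read(p.id, seq, qual))
    return merged, unmerged


# ---------------------------------------------------------------------------
# (iii) quality filtering
# ---------------------------------------------------------------------------

def passes_quality(qual, q_threshold: int = 30, min_hq_fraction: float = 0.80) -> bool:
    """A read passes when the fraction of positions with Q > threshold is not
    below ``min_hq_fraction`` (exactly 80% passes; Q=30 is not high-quality)."""
    if not qual:
        return False
    frac = sum(q > q_threshold for q in qual) / len(qual)
    return not frac < min_hq_fraction


def filter_quality(
    reads: list[Read], q_threshold: int = 30, min_hq_fraction: float = 0.80
) -> tuple[list[Read], list[Read]]:
    kept = [r for r in reads if passes_quality(r.qual, q_threshold, min_hq_fraction)]
    removed = [r for r in reads if not passes_quality(r.qual, q_threshold, min_hq_fraction)]
    return kept, removed


# ---------------------------------------------------------------------------
# (iv) complexity filtering (DUST-style)
# ---------------------------------------------------------------------------

def dust_mask(seq: str, window: int = 64, threshold: float = 20.0) -> list[tuple[int, int]]:
    """Low-complexity intervals by symmetric DUST-style triplet scoring.

    Every window (length <= ``window``) is scored
    ``10 * sum_t c_t (c_t - 1) / 2 / (k - 1)`` over its triplet counts
    (k = number of triplets); windows scoring above ``threshold`` are masked.
    Returned intervals are 0-based half-open and merged.
    """
    n = len(seq)
    if n < 3:
        return []
    masked = []
    step = max(1, window // 2)
    starts = list(range(0, max(n - 2, 1), step))
    if starts[-1] + window < n:
        starts.append(n - window)
    for s in starts:
        w = seq[s : s + window]
        k = len(w) - 2
        if k < 1:
            continue
        counts: dict[str, int] = {}
        n_trip = 0
        for i in range(k):
            t = w[i : i + 3]
            if any(c not in "ACGT" for c in t):
                continue  # ambiguous bases are handled separately
            counts[t] = counts.get(t, 0) + 1
            n_trip += 1
        if n_trip < 2:
            continue
        score = 10.0 * sum(c * (c - 1) // 2 for c in counts.values()) / (n_trip - 1)
        if score > threshold:
            masked.append((s, min(s + len(w), n)))
    # merge overlapping intervals
    masked.sort()
    out: list[tuple[int, int]] = []
    for a, b in masked:
        if out and a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def masked_fraction(seq: str, window: int = 64, threshold: float = 20.0) -> float:
    """Fraction of the read that is ambiguous or DUST-masked (unioned)."""
    if not seq:
        return 1.0
    flags = [c not in "ACGT" for c in seq.upper()]
    for a, b in dust_mask(seq.upper(), window, threshold):
        for i in range(a, b):
            flags[i] = True
    return sum(flags) / len(seq)


def passes_complexity(seq: str, max_masked_fraction: float = 0.40, **dust_kw) -> bool:
    """A read passes unless masked+ambiguous length exceeds 40% (exactly 40%
    passes)."""
    return not masked_fraction(seq, **dust_kw) > max_masked_fraction


def filter_complexity(
    reads: list[Read], max_masked_fraction: float = 0.40
) -> tuple[list[Read], list[Read]]:
    kept = [r for r in reads if passes_complexity(r.seq, max_masked_fraction)]
    removed = [r for r in reads if not passes_complexity(r.seq, max_masked_fraction)]
    return kept, removed


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def run_qc(
    pairs: list[ReadPair],
    min_overlap: int = 10,
    max_mismatch_density: float = 0.25,
    q_threshold: int = 30,
    min_hq_fraction: float = 0.80,
    max_masked_fraction: float = 0.40,
) -> QCResult:
    """Run dedup -> merge -> quality -> complexity and account for every read.

    Merged reads are treated as kept reads and therefore pass through steps
    (iii) and (iv) like any other read.
    """
    res = QCResult()
    res.report.input_pairs = len(pairs)

    unique = deduplicate(pairs)
    res.report.duplicate_pairs_removed = len(pairs) - len(unique)

    merged, unmerged = merge_pairs(unique, min_overlap, max_mismatch_density)
    res.report.pairs_merged = len(merged)

    def _ok(seq: str, qual) -> tuple[bool, str]:
        if not passes_quality(qual, q_threshold, min_hq_fraction):
            return False, "quality"
        if not passes_complexity(seq, max_masked_fraction):
            return False, "complexity"
        return True, ""

    for m in merged:
        ok, why = _ok(m.seq, m.qual)
        if ok:
            res.merged.append(m)
        elif why == "quality":
            res.report.quality_failed += 1
        else:
            res.report.complexity_failed += 1

    for p in unmerged:
        ok_f, why_f = _ok(p.fwd_seq, p.fwd_qual)
        ok_r, why_r = _ok(p.rev_seq, p.rev_qual)
        for ok, why in ((ok_f, why_f), (ok_r, why_r)):
            if not ok:
                if why == "quality":
                    res.report.quality_failed += 1
                else:
                    res.report.complexity_failed += 1
        if ok_f and ok_r:
            res.pairs.append(p)
        elif ok_f:
            res.singletons.append(Read(p.id + "/1", p.fwd_seq, p.fwd_qual))
        elif ok_r:
            res.singletons.append(Read(p.id + "/2", p.rev_seq, p.rev_qual))

    res.report.kept_merged = len(res.merged)
    res.report.kept_pairs = len(res.pairs)
    res.report.kept_singletons = len(res.singletons)
    return res
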