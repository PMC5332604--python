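"""Synthetic viral communities with planted truth.

Generates genus-structured dsDNA-phage-like genome sets, assembly artifacts
(terminal repeats marking circular contigs, near-identical redundant copies)
and paired-end reads with per-base qualities, duplicates and planted
polymorphism, so that every downstream stage of the pipeline can be tested
against known labels.

Model: one random ancestor sequence per community; each genus descends from
the ancestor by uniform point substitutions at ``between_genus_divergence``
substitutions/site, and each genome from its genus ancestor at
``within_genus_divergence``. No indels are introduced by default, so gene
coordinates (non-overlapping ORFs planted on the ancestor) are inherited
unchanged and orthology is traceable through descent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .orfs import Gene, revcomp

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOP_CODONS = {"TAA", "TAG", "TGA"}


# ---------------------------------------------------------------------------
# specs and truth
# ---------------------------------------------------------------------------

@dataclass
class CommunitySpec:
    """Parameters of a genus-structured synthetic community.

    Divergences are expected substitutions per site along the branch from the
    respective ancestor (multiple hits at a site are not modelled).
    """

    n_genera: int = 10
    genomes_per_genus: int | tuple[int, ...] = 4
    genome_length_bp: tuple[int, int] = (15_000, 60_000)
    gc_fraction: float = 0.45
    within_genus_divergence: float = 0.05
    between_genus_divergence: float = 0.5
    gene_density: float = 1.0  # genes per kb
    seed: int = 0

    def genus_sizes(self) -> list[int]:
        """Number of genomes per genus (scalar counts are broadcast)."""
        if isinstance(self.genomes_per_genus, int):
            return [self.genomes_per_genus] * self.n_genera
        return list(self.genomes_per_genus)

    def validate(self) -> None:
        sizes = self.genus_sizes()
        if self.n_genera < 1 or len(sizes) != self.n_genera or min(sizes) < 1:
            raise ValueError("n_genera and genomes_per_genus must be positive")
        lo, hi = self.genome_length_bp
        if not (0 < lo <= hi):
            raise ValueError("invalid genome length range")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must be in [0,1]")
        if not self.within_genus_divergence < self.between_genus_divergence:
            raise ValueError(
                "within_genus_divergence must be smaller than between_genus_divergence"
            )
        if self.within_genus_divergence < 0:
            raise ValueError("divergences must be nonnegative")
        if self.gene_density < 0:
            raise ValueError("gene_density must be nonnegative")


@dataclass(frozen=True)
class PlantedSNP:
    position: int  # 1-based
    ref: str
    alt: str
    frequency: float


@dataclass(frozen=True)
class CircularTruth:
    rotation: int
    repeat_bp: int


@dataclass
class TruthTable:
    """Planted labels for a synthetic community.

    Downstream tests read only from this table, never from generator
    internals.
    """

    genus_of: dict[str, str] = field(default_factory=dict)
    host_group_of: dict[str, str] = field(default_factory=dict)
    genes: dict[str, list[Gene]] = field(default_factory=dict)
    redundant_pairs: list[tuple[str, str]] = field(default_factory=list)
    circular: dict[str, CircularTruth] = field(default_factory=dict)
    snps: dict[str, list[PlantedSNP]] = field(default_factory=dict)

    def labels_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("genome_id\tgenus\thost_group\n")
            for gid, genus in self.genus_of.items():
                fh.write(f"{gid}\t{genus}\t{self.host_group_of.get(gid, '')}\n")


# ---------------------------------------------------------------------------
# sequence-level primitives
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.arange(4, dtype=np.uint8), size=length, p=p)


def mutate(seq: np.ndarray, divergence: float, rng: np.random.Generator) -> np.ndarray:
    """Apply uniform point substitutions at `divergence` per site."""
    out = seq.copy()
    hit = np.flatnonzero(rng.random(len(seq)) < divergence)
    if hit.size:
        # shift by 1..3 in base space: always a different base
        out[hit] = (out[hit] + rng.integers(1, 4, size=hit.size)) % 4
    return out


def _decode(arr: np.ndarray) -> str:
    return BASES[arr].tobytes().decode()


def _encode(seq: str) -> np.ndarray:
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    arr = lut[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError("sequence contains non-ACGT characters")
    return arr


def _random_coding(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    """ATG + (n_codons-2) random sense codons + one stop codon."""
    body = []
    while len(body) < n_codons - 2:
        codon = _decode(_random_sequence(rng, 3, gc))
        if codon not in _STOP_CODONS:
            body.append(codon)
    stop = ["TAA", "TAG", "TGA"][rng.integers(0, 3)]
    return "ATG" + "".join(body) + stop


def _plant_genes(
    ancestor: np.ndarray, density: float, gc: float, rng: np.random.Generator
) -> list[Gene]:
    length = len(ancestor)
    target = int(round(density * length / 1000))
    occupied = np.zeros(length, dtype=bool)
    genes: list[Gene] = []
    attempts = 0
    while len(genes) < target and attempts < 50 * max(target, 1):
        attempts += 1
        n_codons = int(rng.integers(100, 301))
        glen = 3 * n_codons
        if glen >= length:
            continue
        start = int(rng.integers(0, length - glen + 1))
        if occupied[start : start + glen].any():
            continue
        strand = 1 if rng.random() < 0.5 else -1
        coding = _random_coding(rng, n_codons, gc)
        if strand == -1:
            coding = revcomp(coding)
        ancestor[start : start + glen] = _encode(coding)
        occupied[start : start + glen] = True
        genes.append(Gene(f"orf_{len(genes):04d}", start + 1, start + glen, strand))
    genes.sort(key=lambda g: g.start)
    return [Gene(f"orf_{i:04d}", g.start, g.end, g.strand) for i, g in enumerate(genes)]


# ---------------------------------------------------------------------------
# community generation
# ---------------------------------------------------------------------------

def generate_community(spec: CommunitySpec) -> tuple[dict[str, str], TruthTable]:
    """Generate genomes and planted truth for a genus-structured community."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.genome_length_bp
    genus_lengths = [int(rng.integers(lo, hi + 1)) for _ in range(spec.n_genera)]
    max_len = max(genus_lengths)

    ancestor = _random_sequence(rng, max_len, spec.gc_fraction)
    genes = _plant_genes(ancestor, spec.gene_density, spec.gc_fraction, rng)

    genomes: dict[str, str] = {}
    truth = TruthTable()
    sizes = spec.genus_sizes()
    for gi, glen in enumerate(genus_lengths):
        genus = f"genus_{gi + 1:03d}"
        root = mutate(ancestor[:glen], spec.between_genus_divergence, rng)
        genus_genes = [g for g in genes if g.end <= glen]
        for vi in range(sizes[gi]):
            gid = f"g{gi + 1:03d}_v{vi + 1:02d}"
            arr = mutate(root, spec.within_genus_divergence, rng)
            genomes[gid] = _decode(arr)
            truth.genus_of[gid] = genus
            truth.host_group_of[gid] = f"host_{gi + 1:03d}"
            truth.genes[gid] = list(genus_genes)
    return genomes, truth


def make_circular_artifact(genome: str, repeat_bp: int, rotation: int = 0) -> str:
    """Emit a contig emulating the assembly of a circular genome.

    The genome is rotated by ``rotation`` and its first ``repeat_bp`` bases
    are appended at the 3' end, creating the terminal direct repeat by which
    completeness is detected downstream.
    """
    if not 0 < repeat_bp < len(genome):
        raise ValueError("repeat_bp must be in (0, genome length)")
    if not 0 <= rotation < len(genome):
        raise ValueError("rotation out of range")
    rotated = genome[rotation:] + genome[:rotation]
    return rotated + rotated[:repeat_bp]


def add_redundant_copies(
    genomes: dict[str, str],
    truth: TruthTable,
    n_copies: int,
    divergence: float = 0.02,
    seed: int = 0,
) -> None:
    """Plant near-identical duplicate genomes (redundant pairs) in place."""
    rng = np.random.default_rng(seed)
    originals = list(genomes)
    chosen = rng.choice(len(originals), size=min(n_copies, len(originals)), replace=False)
    for idx in sorted(int(i) for i in chosen):
        src = originals[idx]
        dup = f"{src}_dup"
        genomes[dup] = _decode(mutate(_encode(genomes[src]), divergence, rng))
        truth.genus_of[dup] = truth.genus_of.get(src, "")
        truth.host_group_of[dup] = truth.host_group_of.get(src, "")
        truth.genes[dup] = list(truth.genes.get(src, []))
        truth.redundant_pairs.append((src, dup))


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

@dataclass
class ReadSimSpec:
    """Paired-end read simulation parameters (MiSeq-like defaults)."""

    read_length: int = 150
    insert_mean: float = 350.0
    insert_sd: float = 30.0
    coverage: float = 20.0
    per_base_error: float = 0.002
    duplicate_fraction: float = 0.0
    quality_profile: object | None = None  # callable(n, rng) -> int array
    seed: int = 0

    def validate(self) -> None:
        if self.read_length < 1:
            raise ValueError("read_length must be positive")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        for p in (self.per_base_error, self.duplicate_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0,1]")


def _default_quality(n: int, rng: np.random.Generator) -> np.ndarray:
    # mostly high quality with a 10% low-quality tail, emulating tail decay
    q = np.full(n, 38, dtype=int)
    low = rng.random(n) < 0.10
    q[low] = rng.integers(15, 31, size=int(low.sum()))
    return q


@dataclass(frozen=True)
class ReadAlignment:
    """True placement of a simulated pair (0-based starts, forward strand)."""

    read_id: str
    genome_id: str
    fwd_start: int
    rev_start: int
    wrapped: bool


@dataclass
class SimulatedReads:
    pairs: list[tuple[str, str, list[int], str, list[int]]]
    alignments: list[ReadAlignment]
    genome_lengths: dict[str, int]

    def write_fastq(self, path1, path2) -> None:
        from .io import write_fastq

        write_fastq(((rid + "/1", f, fq) for rid, f, fq, _, _ in self.pairs), path1)
        write_fastq(((rid + "/2", r, rq) for rid, _, _, r, rq in self.pairs), path2)

    def write_sam(self, path) -> None:
        """Write true alignments as SAM (wrapped circular pairs are skipped)."""
        by_id = {rid: (f, fq, r, rq) for rid, f, fq, r, rq in self.pairs}
        with open(path, "w") as fh:
            fh.write("@HD\tVN:1.6\tSO:unsorted\n")
            for gid, ln in self.genome_lengths.items():
                fh.write(f"@SQ\tSN:{gid}\tLN:{ln}\n")
            for aln in self.alignments:
                if aln.wrapped:
                    continue
                f, fq, r, rq = by_id[aln.read_id]
                rl = len(f)
                fq_s = "".join(chr(q + 33) for q in fq)
                rq_s = "".join(chr(q + 33) for q in reversed(rq))
                tlen = aln.rev_start + len(r) - aln.fwd_start
                fh.write(
                    f"{aln.read_id}\t99\t{aln.genome_id}\t{aln.fwd_start + 1}\t60\t{rl}M"
                    f"\t=\t{aln.rev_start + 1}\t{tlen}\t{f}\t{fq_s}\n"
                )
                fh.write(
                    f"{aln.read_id}\t147\t{aln.genome_id}\t{aln.rev_start + 1}\t60\t{len(r)}M"
                    f"\t=\t{aln.fwd_start + 1}\t{-tlen}\t{revcomp(r)}\t{rq_s}\n"
                )


def simulate_reads(
    genomes: dict[str, str],
    sim: ReadSimSpec,
    circular: set[str] | None = None,
    snps: dict[str, list[PlantedSNP]] | None = None,
) -> SimulatedReads:
    """Simulate paired-end reads uniformly over the genomes.

    ``circular`` genomes wrap the origin; planted biallelic ``snps`` are
    expressed per sequenced fragment at the given population frequency
    (both mates of a pair are drawn from the same individual fragment).
    """
    sim.validate()
    circular = circular or set()
    snps = snps or {}
    rng = np.random.default_rng(sim.seed)
    qprofile = sim.quality_profile or _default_quality
    rl = sim.read_length

    pairs: list[tuple[str, str, list[int], str, list[int]]] = []
    alignments: list[ReadAlignment] = []
    for gid, seq in genomes.items():
        L = len(seq)
        n_pairs = int(round(sim.coverage * L / (2 * rl)))
        if n_pairs == 0:
            warnings.warn(f"coverage {sim.coverage} implies zero read pairs for {gid}")
            continue
        planted = snps.get(gid, [])
        for k in range(n_pairs):
            insert = int(round(rng.normal(sim.insert_mean, sim.insert_sd)))
            insert = max(rl, min(insert, L))
            if gid in circular:
                p = int(rng.integers(0, L))
            else:
                p = int(rng.integers(0, L - insert + 1))
            wrapped = p + insert > L
            frag = seq[p : p + insert] if not wrapped else seq[p:] + seq[: (p + insert) % L]
            if planted:
                frag_list = None
                for s in planted:
                    off = (s.position - 1 - p) % L if wrapped else s.position - 1 - p
                    if 0 <= off < insert and rng.random() < s.frequency:
                        if frag_list is None:
                            frag_list = list(frag)
                        frag_list[off] = s.alt
                if frag_list is not None:
                    frag = "".join(frag_list)
            fwd = frag[:rl]
            rev = revcomp(frag[-rl:])

            def _errors(read: str) -> str:
                hit = np.flatnonzero(rng.random(len(read)) < sim.per_base_error)
                if not hit.size:
                    return read
                chars = list(read)
                for i in hit:
                    chars[i] = "ACGT"[(("ACGT".index(chars[i])) + int(rng.integers(1, 4))) % 4]
                return "".join(chars)

            fwd, rev = _errors(fwd), _errors(rev)
            fq = [int(q) for q in qprofile(len(fwd), rng)]
            rq = [int(q) for q in qprofile(len(rev), rng)]
            rid = f"{gid}_p{k:06d}"
            pairs.append((rid, fwd, fq, rev, rq))
            alignments.append(
                ReadAlignment(rid, gid, p, (p + insert - rl) % L if wrapped else p + insert - rl, wrapped)
            )

    n_dup = int(round(sim.duplicate_fraction * len(pairs)))
    if n_dup:
        idx = rng.integers(0, len(pairs), size=n_dup)
        for j, i in enumerate(idx):
            rid, f, fq, r, rq = pairs[int(i)]
            dup_id = f"{rid}_dup{j:04d}"
            pairs.append((dup_id, f, list(fq), r, list(rq)))
            src = alignments[int(i)]
            alignments.append(
                ReadAlignment(dup_id, src.genome_id, src.fwd_start, src.rev_start, src.wrapped)
            )
    return SimulatedReads(pairs, alignments, {g: len(s) for g, s in genomes.items()})
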