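"""Translation helpers and a naive ORF caller.

The pipeline needs per-gene protein sequences in two situations: translating
planted gene coordinates from the community simulator (or a GFF3 file), and
calling ORFs de novo on genomes that come without annotation. The ORF caller
is deliberately simple — longest ATG-to-stop open reading frames on both
strands — and is not a gene predictor.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class Gene:
    """A protein-coding gene on a nucleotide sequence.

    ``start``/``end`` are 1-based inclusive coordinates on the forward strand;
    ``strand`` is ``+1`` or ``-1``.
    """

    id: str
    start: int
    end: int
    strand: int

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad gene coordinates {self.start}..{self.end}")
        if self.strand not in (1, -1):
            raise ValueError("strand must be +1 or -1")


def translate(seq: str) -> str:
    """Translate a nucleotide string (frame +1), stops rendered as ``*``.

    Trailing bases that do not fill a codon are ignored.
    """
    usable = len(seq) - len(seq) % 3
    return str(Seq(seq[:usable]).translate())


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def gene_nucleotides(genome: str, gene: Gene) -> str:
    sub = genome[gene.start - 1 : gene.end]
    return sub if gene.strand == 1 else revcomp(sub)


def gene_protein(genome: str, gene: Gene, strip_stop: bool = True) -> str:
    aa = translate(gene_nucleotides(genome, gene))
    if strip_stop and aa.endswith("*"):
        aa = aa[:-1]
    return aa


def call_orfs(genome: str, min_codons: int = 100) -> list[Gene]:
    """Naive ORF calling: ATG..stop spans of >= min_codons on both strands.

    Within one frame, nested starts are collapsed to the longest ORF ending
    at each stop. Coordinates include the stop codon.
    """
    orfs: list[Gene] = []
    n = len(genome)
    for strand, seq in ((1, genome), (-1, revcomp(genome))):
        for frame in range(3):
            start_pos: int | None = None
            for i in range(frame, n - 2, 3):
                codon = seq[i : i + 3]
                if codon == "ATG" and start_pos is None:
                    start_pos = i
                elif codon in STOPS and start_pos is not None:
                    ncod = (i + 3 - start_pos) // 3
                    if ncod >= min_codons:
                        if strand == 1:
                            s, e = start_pos + 1, i + 3
                        else:  # map back to forward-strand coordinates
                            s, e = n - (i + 3) + 1, n - start_pos
                        orfs.append(Gene(f"orf_{len(orfs)}", s, e, strand))
                    start_pos = None
    orfs.sort(key=lambda g: (g.start, g.end))
    return [Gene(f"orf_{i:04d}", g.start, g.end, g.strand) for i, g in enumerate(orfs)]


def write_gff3(genes: dict[str, list[Gene]], path) -> None:
    """Write planted/called genes as GFF3, one CDS feature per gene."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for seqid, glist in genes.items():
            for g in glist:
                strand = "+" if g.strand == 1 else "-"
                fh.write(
                    f"{seqid}\tevgtools\tCDS\t{g.start}\t{g.end}\t.\t{strand}\t0\tID={g.id}\n"
                )


def read_gff3(path) -> dict[str, list[Gene]]:
    genes: dict[str, list[Gene]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] not in ("CDS", "gene"):
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            gid = attrs.get("ID", f"{f[0]}:{f[3]}-{f[4]}")
            genes.setdefault(f[0], []).append(
                Gene(gid, int(f[3]), int(f[4]), 1 if f[6] != "-" else -1)
            )
    return genes
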