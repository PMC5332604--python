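# Methods

This note documents the models, parameter choices and numerical conventions
behind `evgtools`, and what the synthetic-data validation does and does not
establish about real viromes.

## Synthetic communities

The generator emulates the population structure of a genus-resolved dsDNA
virus catalog. One random ancestor sequence is drawn per community with base
probabilities set by `gc_fraction` (default 0.45, a mid-range marine phage
composition). Non-overlapping protein-coding genes (ATG + random sense
codons + stop, 100–300 codons, either strand) are planted on the ancestor at
`gene_density` genes/kb (default 1.0, roughly the coding density of tailed
phage genomes at our gene-length distribution). Each genus descends from the
ancestor by uniform point substitutions at `between_genus_divergence`
(default 0.5 substitutions/site) and each genome from its genus ancestor at
`within_genus_divergence` (default 0.05); substitutions always change the
base and multiple hits are not modelled, so the parameter is the per-branch
expected difference fraction, not an evolutionary distance. No indels are
introduced by default; gene coordinates are therefore inherited unchanged
and orthology is traceable through descent, which keeps alignment oracles
exact. Genome lengths default to 15–60 kb, the size regime of the genome
catalog (only contigs > 10 kb are admitted downstream).

Assembly artifacts are planted explicitly: `make_circular_artifact` rotates
a genome and appends its first *r* bases (the terminal direct repeat an
assembler produces for a circular template), and `add_redundant_copies`
plants near-identical duplicates (default 2% divergence, comfortably inside
the ≥ 95% redundancy rule). Read simulation draws uniform fragments
(normal insert, default 350 ± 30 bp; 2 × 150 bp mates, MiSeq-like), wraps
the origin for circular genomes, expresses planted biallelic sites per
fragment at their population frequency, injects uniform base errors
(default 2 × 10⁻³), draws per-base qualities from a profile (default: Q38
with a 10% tail at Q15–30), and appends exact duplicate pairs at
`duplicate_fraction`.

What the generator does **not** emulate: position-dependent error spectra,
chimeric fragments, coverage biases (GC or origin-linked), indel
polymorphism, and non-uniform abundance (a lognormal option exists for
fragment counts only through per-genome coverage choices). Passing tests on
these communities therefore validate the *logic* of each stage — threshold
semantics, score normalization, clustering and estimator algebra — not
robustness to instrument-specific artifacts.

## Read quality control

Fixed order: exact-duplicate pair removal → overlap merging → quality
filter → complexity filter. Merging scans all 3′ overlaps ≥ `min_overlap`
(default 10) and keeps the lowest-mismatch-density overlap if its density is
≤ 0.25 (the published defaults of the common merger); disagreeing bases take
the higher-quality call. The quality rule removes a read when the fraction
of positions with Q > 30 falls below 0.80 — inequalities are read strictly,
so Q = 30 is not high quality and exactly 80% passes. The complexity rule
unions ambiguous bases with DUST-style low-complexity windows (symmetric
triplet scoring, window 64, score threshold 20, ambiguous triplets excluded
from scoring) and removes the read above 40% masked; exactly 40% passes.
Merged reads are treated as kept reads and pass through the two filters like
any other read; when one mate fails, the other is demoted to the singleton
pool. Every input read ends in exactly one of kept-merged / kept-paired /
kept-singleton / removed, an invariant the report enforces.

## Circularity and redundancy

Terminal repeats are found by exact-match seeding: k-mers (k = 15) from the
first five positions of the contig are located in a 3′ window of
min(5 kb, 20% of the contig), each hit implying an overlap length that is
then scored ungapped over the full overlap. The call is circular iff the
best overlap is ≥ 50 bp at identity strictly > 94%; the repeat is trimmed
from the reported genome length (both lengths are kept). The procedure is
invariant to rotation and reverse complement of the underlying circular
genome. Contigs shorter than twice the minimum overlap return a
not-evaluable call rather than a negative one.

Redundancy projects nucleotide HSPs onto the shorter genome; coverage is the
interval union (overlap counted once) and identity the alignment-length-
weighted mean over all HSPs (the weighting is our deterministic reading of
"average identity"). Pairs at ≥ 80% coverage and ≥ 95% identity are
redundant; single-linkage components are collapsed to their longest member
(ties broken lexicographically; both conventions configurable).

## S_G and its computation

Local alignments come from the NCBI BLAST+ binaries (tblastx, blastn,
blastp; single-threaded, tabular output), the same programs behind the
original workflow; the package parses and re-emits the standard 12-column
tabular format so external search results can substitute bit-exactly at the
scoring stage. The Karlin–Altschul bit-score arithmetic is exposed as
`bitscore_from_raw` (ungapped BLOSUM62 λ = 0.3176, K = 0.134 by default;
gapped λ = 0.267, K = 0.041 optional).

Per direction, HSPs are tiled greedily by descending bit score; an HSP is
discarded when its query interval overlaps any selected HSP by more than
half of its own span (the > 50% rule is our aggregation choice — the
endpoint properties hold under any sane tiling). The two directional sums
are averaged and normalized by the smaller self-score (geometric-mean
normalization is a config option; both give S_G = 1 for identical genomes
and 0 for no hits). Self-similarity is 1 by construction on the matrix
diagonal and exactly 1 when computed between identical copies, because the
tiled HSP sets coincide.

At community scale the all-vs-all search is restricted to candidate pairs
sharing at least two exact nucleotide 18-mers, grouped into connected
components with one search per component; non-candidate pairs are assigned
S_G = 0. At genus-level divergence (~10% pairwise) thousands of 18-mers
survive per pair, while unrelated sequences essentially never share one, so
the prefilter is recall-safe for the clustering regime it serves; it would
not be appropriate for detecting remote (< ~40% identity) nucleotide
relationships, where the exhaustive mode (`candidates="all"`, the default)
should be used. A test confirms prefiltered and exhaustive matrices agree
to < 0.05 on a mixed community.

## Trees

BIONJ is implemented directly (Q-criterion pair choice, variance-weighted
reduction with λ clamped to [0,1], variance matrix initialized to the
distances). Ties in the Q minimization take the lowest index pair; negative
branch estimates are clamped to zero with the deficit moved to the sibling.
On additive matrices the implementation reproduces the generating tree
topology (RF = 0) and path lengths to < 1e-9, which the acceptance suite
verifies over 200 random trees (n ≤ 12). Midpoint rooting and Newick I/O
use dendropy; two-leaf trees are already midpoint-split by construction.
Stored branch lengths are untransformed; log-scaling for display is a
separate export (`log_scaled_lengths`, log10(1 + d/ε)).

## gOTUs and richness

Average-linkage clustering runs on 1 − S_G and cuts the dendrogram at
1 − cutoff, so cluster members have average inter-member similarity at
least the cutoff; raising the cutoff only refines the partition. The
adjusted Rand index is computed from the contingency-table closed form
(cross-checked against scikit-learn) and the cutoff scan walks a 0.01-step
grid (the coarser 0.1–0.9 grid is available by passing an explicit grid),
reporting the smallest argmax cutoff. Chao1 uses the bias-corrected form
S_obs + f₁(f₁−1)/(2(f₂+1)) (classical form optional, and used only when
f₂ > 0); rarefaction is the analytic hypergeometric expectation with
percentile confidence intervals from 100 bootstrap resamples of genomes.

## Variation

Pileups count only aligned bases with Q > 30; positions with ≥ 5× such
coverage are evaluable. The six SNP criteria are applied to the second-most-
frequent base (ties broken in fixed A < C < G < T order) with "more than"
strict, which yields the implication lattice vi ⇒ ii ∧ iii, v = ii ∨ iii,
iv ⇒ iii ⇒ i. Nucleotide diversity uses the unbiased per-site estimator
(C/(C−1))(1 − Σ p²) — algebraically identical to the all-pairs mismatch
fraction among sampled reads, which a property test confirms to 1e-12 — and
genome π is the mean over evaluable sites, reported in %. SNP rates and π
share the ≥ 5× denominator so the two statistics are computed on the same
site set; this is a documented interpretation, as is applying the filters to
merged reads in QC.

## Hosts and abundance

Precision estimation excludes genomes lacking a same-group or different-
group partner (so a reference set in which every labelled genome is
eligible yields exactly two scores per genome). The cutoff chosen for a
target precision is the smallest grid value (0.0001 steps over the observed
range, matching the four-decimal granularity of the published cutoffs)
whose precision exceeds the target and stays above it at all larger defined
cutoffs; comparisons at the cutoff are strict. BBH orthologs break ties by
longer alignment then lexicographic id; B_g ≥ 60% is reported as nearly
complete colinearity.

FPKM counts each merged read or read pair as one fragment assigned to its
best-scoring genome (ties split equally; the counting unit is our choice,
documented because the source workflow does not state one). gOTU abundance
first collapses declared replicate sample groups to their mean, then sums
member genomes per sample and averages across samples; normalized abundance
scales to a 100% column. Recruitment applies expect < 1e-3 first, then
≥ 60% identity and ≥ 80% query coverage.

## Problem sizes used in validation

The test and acceptance runs use desk-scale instances chosen as the
smallest sizes that exercise each property: 20-kb single genomes for the
similarity endpoints, a 345-genome / 82-genus community at 15 kb and
0.05/0.5 divergence for the cutoff-scan calibration (mirroring the size of
the published calibration set), 20 independent 20-genome communities for
host-precision recovery, 10,000 random pileup columns for the SNP lattice,
and 200 random additive matrices (n ≤ 12) for tree reconstruction. The
published catalog-scale counts (thousands of genomes, hundreds of gOTUs)
depend on large external sequence sets and are out of scope here.

## Known limitations

- The aligner is BLAST+; scores depend mildly on its version and on database
  size through the expect threshold (per-component searches see smaller
  databases than one global search, shifting marginal HSPs).
- The k-mer prefilter makes distant nucleotide-level pairs score 0 by fiat
  in `candidates="auto"` mode.
- The ORF caller is naive (longest ATG-to-stop) and is not a substitute for
  a gene predictor on real data; planted-gene coordinates or GFF3 input are
  preferred.
- Read mapping itself is out of scope: variation statistics consume SAM/BAM
  from any mapper, the simulator's true placements, or a pileup TSV.
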