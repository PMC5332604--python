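# evgtools

Tools for turning marine virome assemblies into complete viral genomes and
genome-based ecology: circular (complete) contig detection, dereplication,
genome-wide translated-alignment similarity (S<sub>G</sub>), BIONJ proteomic
trees, genus-level genomic OTUs (gOTUs), similarity-based host prediction,
intra-population SNP/nucleotide-diversity statistics, and FPKM abundance and
read-recruitment summaries. A synthetic community generator plants full
ground truth (genus labels, host groups, terminal repeats, redundant copies,
polymorphic sites) so every stage can be validated without external data.

The intended users are viral-metagenomics researchers who assemble dsDNA
virus genomes from shotgun viromes and need a reproducible, testable
implementation of the standard genome-catalog workflow.

## The core statistic

For genomes *A* and *B*, tBLASTx HSPs from each search direction are reduced
to a tiling score: HSPs are selected greedily by descending bit score,
skipping any HSP whose query interval overlaps an already-selected HSP by
more than half its own span, and the selected bit scores are summed; the two
directions are averaged into raw(*A*,*B*). The genome-wide similarity is

&nbsp;&nbsp;&nbsp;&nbsp;S<sub>G</sub>(A,B) = raw(A,B) / min(raw(A,A), raw(B,B)), clipped to [0,1],

so S<sub>G</sub> = 1 for identical genomes and 0 when the translated search
finds no similarity. Trees are built with BIONJ on d = 1 − S<sub>G</sub> and
midpoint rooted; gOTUs are average-linkage clusters cut at an S<sub>G</sub>
cutoff chosen by maximizing the adjusted Rand index against a reference
genus classification (cutoff ≈ 0.15 behaves as a viral genus level).

Other implemented statistics: circularity (terminal repeat ≥ 50 bp at
> 94% identity), redundancy (merged HSPs covering ≥ 80% of the shorter
genome at ≥ 95% mean identity, single-linkage dereplication), six SNP
criteria at ≥ 5× high-quality (Q > 30) coverage, nucleotide diversity
π = mean over sites of (C/(C−1))(1 − Σ p<sub>b</sub>²), bias-corrected
Chao1 with analytic rarefaction, bidirectional-best-hit colinearity
B<sub>g</sub>, and FPKM = count / ((length/10³)(library/10⁶)).

## Worked example

```python
from evgtools import CommunitySpec, generate_community, sg_matrix, scan_cutoffs
from evgtools.community import make_circular_artifact
from evgtools.catalog import detect_circular

spec = CommunitySpec(n_genera=3, genomes_per_genus=3,
                     genome_length_bp=(12_000, 15_000), seed=11)
genomes, truth = generate_community(spec)

sg = sg_matrix(genomes)
print(round(sg.loc["g001_v01", "g001_v02"], 3))   # 0.771  (same genus)
print(round(sg.loc["g001_v01", "g002_v01"], 3))   # 0.0    (different genus)

ev = scan_cutoffs(sg, truth.genus_of)
print(ev.best_cutoff, ev.best_ari)                # 0.01 1.0

contig = make_circular_artifact(genomes["g001_v01"], 60)
call = detect_circular("g001_v01", contig)
print(call.is_circular, call.overlap_length, call.trimmed_length)
# True 60 12401
```

Genomes of the same planted genus (5% divergence each from their genus
ancestor) score S<sub>G</sub> ≈ 0.77 while genomes of different genera (50%
divergence) find no translated alignment and score 0, so the cutoff scan
recovers the planted genus partition exactly (ARI = 1). The 60-bp terminal
repeat added by the assembly-artifact helper is detected and trimmed back to
the original 12,401-bp genome.

The same workflow is scriptable from the shell:

```bash
evg simulate --n-genera 3 --genomes-per-genus 3 --seed 11 \
    --out-fasta community.fa --out-labels labels.tsv
evg sg --genomes community.fa --out sg.mat
evg tree --sg-matrix sg.mat --out tree.nwk
evg gotu --sg-matrix sg.mat --truth labels.tsv --out gotus.tsv
```

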