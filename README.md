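# immucontig

Tools for assessing how well a genome assembly and its annotation capture
**complex immune gene families** — MHC, NK-cell receptors (LRC/NKC),
T-cell receptor and immunoglobulin loci, TLRs and cytokines. These
families are duplicated, polymorphic and clustered, which makes them the
first casualties of short-read assemblies and automated annotation
pipelines, even in genomes whose BUSCO scores look excellent. The
intended users are groups who manually curate immune (or other complex)
gene families in non-model genomes and want quantitative, reproducible
statements about annotation concordance and assembly fragmentation.

## What it computes

**Annotation concordance.** For each manually curated gene `g`, the
overlap fraction against an automated annotation `A` is

```
ov(g) = | span(g) ∩ ⋃_{m∈A, same scaffold} span(m) | / | span(g) |
```

i.e. the fraction of the curated gene's bases covered by the union of all
automated models (pipelines fragment one gene into several models, so all
are credited). Genes are binned into deciles and flagged *correct*
(ov ≥ 0.90), *poor* (ov ≤ 0.10, includes missing), *missing* (ov = 0) and
*not accurately annotated* (ov ≤ 0.80). An exon-level variant compares
exon base sets, which credits V segments recovered as exons of some other
model.

**Gene-set L50/L90.** The contiguity of a curated gene set is the minimum
number of scaffolds that together carry 50% (L50) or 90% (L90) of its
genes, ranking scaffolds by gene count. Intact clusters give L90 near the
number of chromosomes carrying the families; fragmented assemblies give
L90 in the tens to hundreds. Per-family reports add orphan-scaffold
counts, the share of genes on the top scaffold, scaffolds below length
thresholds, and interleaving flags (e.g. LRC/extended-LRC mixed on one
scaffold, a misassembly signature). Classic assembly N50/L50 is included.

**Homology-hit curation.** Post-processing of BLAST tabular and HMMER
per-domain hits into candidate gene models: inclusive e-value ≤ 10
filter, merging of overlapping hits into domain calls, chaining of
domains within 5 kbp into multi-exon genes (the IGSF-domain rule for LRC
genes), RSS flanking checks for V segments, a retention gate on top
database hits, and positional 5′→3′ naming of duplicates.

**Simulation.** A generator produces truth genomes with clustered ~10 kbp
gene families and V-segment arrays, fragments them to a target contig
N50, rescaffolds with controllable inversion/misjoin error rates, and
degrades annotations with a Beta-distributed per-gene coverage model —
so every statistic above can be validated against known ground truth.

## Worked example

```
$ python examples/04_simulation.py
truth genome: 4 chromosomes, 417 genes, gene_L90=4

contig N50 target   mean gene_L90 (5 seeds)
        50,000 bp     47.0
       500,000 bp      7.6
     5,000,000 bp      4.0

error-free scaffolding restores gene_L90=4 (equals truth)

degraded annotation (miss 10%, Beta(9,1) coverage):
  measured missing = 7.4%  (generated: 10%)
  mean overlap of annotated genes = 0.901  (Beta mean: 0.900)
```

Reading: the truth genome keeps its gene families on 4 chromosomes
(L90 = 4). Fragmenting it to a 50 kbp contig N50 — short-read territory —
scatters 90% of the genes across ~47 contigs, while a 5 Mbp N50 preserves
the clusters; rejoining the contigs without errors restores the truth
statistic exactly. The concordance module then reads back the annotation
degradation parameters it was given.

The other examples (`examples/01_concordance.py`, `02_contiguity.py`,
`03_locus_discovery.py`) each print a small end-to-end run of one module.

A thin CLI wraps the same functions:

```
immucontig simulate --seed 3 --out-dir sim/
immucontig contiguity --annotation sim/truth.tsv --fai sim/truth.fai --out-dir cont/
immucontig concordance --manual sim/truth.tsv --auto sim/auto.gff3 --out-dir conc/
immucontig report --manual sim/truth.tsv --auto sim/auto.gff3 --fai sim/truth.fai --out-dir rep/
```

## Formats

Curated tables are TSV/CSV (1-based inclusive coordinates, configurable
column mapping); automated annotations GFF3; scaffold lengths `.fai` or
two-column TSV; homology hits BLAST `-outfmt 6` and HMMER `--domtblout`.
Everything is converted to 0-based half-open coordinates internally and
written back as GFF3/BED/TSV. See `docs/methods.md` for the statistical
and modelling details.
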