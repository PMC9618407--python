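# Methods

## Coordinates

All internal coordinates are 0-based, half-open, on the forward reference
orientation. Curated tables and GFF3 (1-based inclusive), BED (0-based
half-open), BLAST subject coordinates (1-based inclusive, reversed on
minus-strand hits) and HMMER envelope coordinates (1-based inclusive) are
converted exactly once, at the I/O boundary. Readers reject `start > end`
with the offending row number and never silently drop records; unknown
family labels map to `other` with a warning so row counts are preserved.
Family labels are resolved through a user-extensible synonym table,
because curated spreadsheets write families as prose.

## Concordance model

The unit of assessment is the *manually curated gene*: its length is the
denominator, and 0 means the curated gene is absent from the automated
annotation. Coverage accumulates over the union of **all** intersecting
automated models rather than the single best one, because automated
pipelines routinely fragment one gene into several models; union coverage
is also monotone under adding models, which the property tests exploit.
Overlap is strand-agnostic by default (automated strand calls are
unreliable exactly where assemblies invert contigs); a `stranded` flag
enables strand-matched overlap.

Thresholds are inclusive: correct ≥ 0.90, poor ≤ 0.10, missing = 0, not
accurately annotated ≤ 0.80. `pct_poor` includes the missing genes; the
exclusive reading is recoverable as `pct_poor − pct_missing`, and both are
always reported. The decile histogram gives bin `0` to exactly-zero
overlaps and half-open bins `(0,10] … (90,100]` otherwise, so the bins
partition the gene set.

At exon level, either side falls back to its gene span when it carries no
exon structure. This is deliberate: a span-only automated model that
covers a curated exon still counts, which is what "recovered at the exon
level" means for V segments annotated as exons of some other gene model.

## Gene-set L50/L90

`gene_set_L(S, f)` is the smallest number of scaffolds that together
carry at least fraction `f` of the genes in `S`, ranking scaffolds by
gene count (ties by scaffold id, ascending, for determinism). Greedy
ranking is provably optimal for this objective — any subset of `k`
scaffolds carries at most as many genes as the `k` most gene-rich ones —
and the tests assert equality with a brute-force subset search.

The threshold comparison is exact rational arithmetic: a fraction given
as the float `0.9` is interpreted at its printed decimal value (9/10),
since `0.9 × 10` exceeds 9 in binary floating point and would silently
shift L90 by one scaffold on sets whose gene count is a multiple of ten.

Each gene is assigned to exactly one scaffold. Genes split across
contigs/scaffolds (as produced by the simulator) carry a parent id and a
designated *primary* fragment — the longest — and only primaries are
counted, so a fragmented gene is one gene, not several.

An *orphan* is a scaffold carrying exactly one gene of a family,
regardless of its distance to the main cluster. The interleaving flag
reports two families as mixed on a scaffold when, reading genes in
coordinate order, the family label switches more than once (i.e. the
scaffold cannot be cut into one contiguous block per family).

The gene-weighted scaffold-length quantile (the largest length `L` such
that ≥ `p` of genes lie on scaffolds ≥ `L`) is the order statistic at
rank ⌈pN⌉ of the per-gene scaffold lengths sorted descending, again with
exact rational rank arithmetic.

## Homology-hit curation

* **Filter**: e-value ≤ 10, inclusive. The permissive threshold is part
  of the method's intent (exclude nothing potentially real at the search
  stage); removed hits are counted and logged.
* **Merge**: hits on one scaffold, strand and domain label union when
  they overlap or abut (`next.start == prev.end`); a 1 bp gap separates.
* **Chain**: domains whose inter-domain gap (`next.start −` running max
  end) is ≤ 5 kbp become exons of one candidate. The running-max rule
  makes chaining exactly equal to transitive-closure clustering of the
  pairwise "within 5 kbp" relation, independent of input order and
  idempotent. 5 kbp is the IGSF-domain rule for LRC genes and is the
  per-family default; chaining is strand-aware by default with a switch,
  since the underlying practice does not state strandedness.
* **RSS pairing**: a V-segment candidate is flanked when an RSS call on
  the same strand starts within 60 bp downstream of its 3′ end (strand
  dependent). 60 bp is a package default chosen because the RSS
  heptamer–spacer–nonamer motif is 28–39 bp and abuts the segment; it is
  configurable.
* **Retention gate**: a candidate is kept iff its externally produced
  top-hit label set intersects the allow list (swissprot NK, marsupial
  NK, PF00047, PF00059 by default). Consuming a precomputed table keeps
  the module deterministic and offline-testable. Candidates absent from
  the table are rejected with an explicit reason.
* **Naming**: duplicates are named `prefix1..prefixN` by ascending start
  on the plus orientation; ties break by end then input order with a
  warning.

Where BLAST and HMMER evidence overlap, the module unions it and keeps
per-hit provenance rather than imposing a priority between search tools.

## Simulator

The generator emulates the mechanisms linking assembly quality to
annotation quality, not any particular sequencing instrument:

* **Truth genomes** place family clusters on designated chromosomes:
  gene lengths normal with configurable mean and CV (default mean
  10 kbp — the typical immune gene — CV 0.15; a CV of 0 is exactly
  degenerate), exponential intergenic gaps (default mean 5 kbp), strand
  random, optional evenly spaced exons. The default configuration holds
  417 genes in 12 clusters (MHC I/II/III, cytokines, TLR, NKC,
  LRC + extended LRC, IG/TCR constant, and short dense V-segment arrays
  of 0.5–0.6 kbp segments) on 4 chromosomes of 8 Mbp.
* **Fragmentation** cuts chromosomes at uniform random breakpoints,
  adjusting the breakpoint count until the realised contig N50 lies in
  [0.5×, 2×] of the target (uniform cutting is the simplest model that
  produces the observed cluster-scattering behaviour; no generative law
  for contig ends is claimed). Genes hit by a breakpoint become partial
  fragments whose lengths sum to the truth length.
* **Scaffolding with errors** re-joins each chromosome's contigs in
  order, without gap bases. At each join the incoming contig is inverted
  with probability `inversion_rate` (gene strands flip), and with
  probability `misjoin_rate` it is *swapped* with the next contig of
  another chromosome, so contig content is conserved and, at misjoin
  rate 1, every multi-contig scaffold provably mixes chromosomes.
  Fragments that land back adjacent in one orientation are re-fused, so
  error-free scaffolding restores truth coordinates and L statistics
  exactly. Default error rates (0.1 inversions, 0.02 misjoins per join)
  are placeholders for property tests, not estimates of any scaffolder.
* **Annotation degradation** drops each gene with probability
  `miss_rate`, else covers a Beta(α, β) fraction of its span anchored at
  a uniformly chosen end, optionally split into ≤ 3 abutting models
  (coverage unchanged). Expected mean overlap of retained genes is
  α/(α+β), giving closed-form targets for calibration tests.
  `overlap_beta=None` expresses the degenerate full-coverage case.

Every stage draws from `default_rng([seed, stage_id])` (per-gene
substreams in the degradation stage, so toggling the split option cannot
perturb other genes' draws). Reruns are byte-identical, not merely
statistically equivalent.

What the simulator does **not** model: sequence content (FASTA output,
when requested, is a fixed periodic pattern for format exercises only),
read-level errors, repeat-induced breakpoint clustering, gap bases in
scaffolds, and contact-matrix mechanics of HiC (only its end effects,
inversions and misjoins). Passing tests therefore demonstrate the
statistics and the degradation mechanisms, not realism of any particular
assembler's error spectrum.

## Problem sizes and verification

Tests and the acceptance script run the default 4 × 8 Mbp, 417-gene
configuration: large enough that clusters straddle many 50 kbp contigs
and small enough for the whole suite to run in seconds. Fragmentation
monotonicity uses contig N50 targets of 50 kbp, 500 kbp and 5 Mbp;
parameter recovery uses miss rate 0.1 and Beta(9, 1) coverage over 5–10
seeds and checks agreement within three Monte-Carlo standard errors of
the respective estimators. Published per-species L90 values and gene
counts can be recomputed with `gene_set_L` from the originating study's
supplementary coordinate table when a copy is placed at
`data/additional_file1.tsv` (see `tests/test_acceptance.py` for the
expected layout); the table is journal supplementary material and is not
redistributed here.

## Known limitations

* Concordance is coordinate-based; no identifier matching, no
  transcript-level sensitivity/specificity.
* The GFF3 feature policy (gene > mRNA > exon-union) covers the common
  dialects of Fgenesh++/MAKER/NCBI exports but not pathological files
  mixing policies within one file.
* `cluster_report` treats a family's genes on one scaffold as one
  cluster; multi-cluster-per-scaffold layouts are summarised by the max
  inter-gene gap instead of being split.
* The simulator's misjoin swap preserves contig counts per scaffold;
  real misjoins also change scaffold counts.
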