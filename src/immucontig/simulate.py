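"""Synthetic truth genomes, degraded assemblies and annotation pairs.

The generator reproduces, at desk scale, the mechanisms by which assembly
quality degrades immune-gene annotation:

* a *truth genome* carries clustered gene families (duplicated ~10 kbp
  genes, short V-segment arrays) laid out on a few chromosomes;
* *fragmentation* cuts chromosomes at uniform random breakpoints until a
  target contig N50 is realised — genes hit by a breakpoint are lifted as
  partial fragments, the way short-read contigs truncate long genes;
* *error-prone scaffolding* re-joins contigs, occasionally inverting the
  incoming contig or splicing in a contig from another chromosome, the
  characteristic failure modes of contact-map scaffolding on short
  contigs;
* *annotation degradation* emulates an automated pipeline: each gene is
  missed with some probability, otherwise replaced by model(s) covering a
  Beta-distributed fraction of its span, anchored at a random end.

Only lengths and coordinates are generated, never sequence. Each stage
draws from its own pseudo-random stream derived from ``(seed, stage)`` so
stages are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import _union_intervals
from .model import (
    AnnotationSet,
    AssemblyIndex,
    Family,
    GeneAnnotation,
    GenomicInterval,
    Strand,
    parse_family,
)

__all__ = [
    "FamilyConfig",
    "SimulationConfig",
    "TruthSet",
    "FragmentedAssembly",
    "ScaffoldedAssembly",
    "default_config",
    "simulate_truth",
    "fragment_assembly",
    "scaffold_with_errors",
    "degrade_annotation",
]

_STAGE_IDS = {"truth": 1, "fragment": 2, "scaffold": 3, "degrade": 4}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STAGE_IDS[stage]])


@dataclass(frozen=True)
class FamilyConfig:
    """Layout of one clustered gene family on the truth genome."""

    name: str
    gene_count: int
    gene_length_mean: float = 10_000.0  # the typical immune gene is ~10 kbp
    gene_length_cv: float = 0.15
    exons_per_gene: int = 1
    intergenic_mean: float = 5_000.0
    cluster_scaffold: str = "chr1"


@dataclass(frozen=True)
class SimulationConfig:
    families: Tuple[FamilyConfig, ...]
    seed: int
    chromosome_count: int = 4
    chromosome_length: int = 8_000_000
    target_contig_N50: int = 500_000
    inversion_rate: float = 0.1
    misjoin_rate: float = 0.02
    annotation_miss_rate: float = 0.1
    annotation_overlap_beta: Optional[Tuple[float, float]] = (9.0, 1.0)

    def __post_init__(self) -> None:
        for rate in (self.inversion_rate, self.misjoin_rate, self.annotation_miss_rate):
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"rate {rate} outside [0, 1]")
        if self.chromosome_length < 1 or self.chromosome_count < 1:
            raise ValueError("chromosome count/length must be positive")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def default_config(seed: int, **overrides) -> SimulationConfig:
    """Study-scale default layout: clustered MHC / NK-receptor / cytokine
    families of ~10 kbp genes plus short, dense V-segment arrays, on 4
    chromosomes of 8 Mbp."""
    families = (
        FamilyConfig("MHC_I", 20, cluster_scaffold="chr1"),
        FamilyConfig("MHC_II", 15, cluster_scaffold="chr1"),
        FamilyConfig("MHC_III", 35, cluster_scaffold="chr1"),
        FamilyConfig("cytokine", 70, cluster_scaffold="chr2"),
        FamilyConfig("TLR", 10, cluster_scaffold="chr2"),
        FamilyConfig("NKC", 15, cluster_scaffold="chr3"),
        FamilyConfig("LRC", 40, exons_per_gene=4, cluster_scaffold="chr3"),
        FamilyConfig("LRC_ext", 10, cluster_scaffold="chr3"),
        FamilyConfig("IG_C", 12, cluster_scaffold="chr4"),
        FamilyConfig(
            "IG_V", 100, gene_length_mean=600, gene_length_cv=0.2,
            intergenic_mean=2_000, cluster_scaffold="chr4",
        ),
        FamilyConfig("TCR_C", 10, cluster_scaffold="chr4"),
        FamilyConfig(
            "TCR_V", 80, gene_length_mean=500, gene_length_cv=0.2,
            intergenic_mean=2_000, cluster_scaffold="chr4",
        ),
    )
    return SimulationConfig(families=families, seed=seed, **overrides)


@dataclass(frozen=True)
class TruthSet:
    assembly: AssemblyIndex
    annotation: AnnotationSet
    config: SimulationConfig


def _gene_exons(span: GenomicInterval, n_exons: int) -> Tuple[GenomicInterval, ...]:
    if n_exons <= 1:
        return ()
    # equal exons separated by equal introns filling the span
    unit = span.length // (2 * n_exons - 1)
    if unit < 1:
        return ()
    exons = []
    for k in range(n_exons):
        lo = span.start + 2 * unit * k
        hi = lo + unit if k < n_exons - 1 else span.end
        exons.append(GenomicInterval(span.scaffold, lo, hi, span.strand))
    return tuple(exons)


def simulate_truth(config: SimulationConfig) -> TruthSet:
    """Generate the truth genome: chromosomes of fixed length carrying the
    configured family clusters, genes placed left to right with exponential
    intergenic gaps. Deterministic for a fixed seed."""
    rng = _rng(config.seed, "truth")
    margin = 1_000
    chroms = {f"chr{i + 1}": config.chromosome_length for i in range(config.chromosome_count)}
    cursors = {name: margin for name in chroms}
    genes: List[GeneAnnotation] = []
    for fc in config.families:
        scaffold = fc.cluster_scaffold
        if scaffold not in chroms:
            raise ValueError(f"cluster_scaffold {scaffold!r} not among chromosomes")
        if cursors[scaffold] > margin:  # separate clusters sharing a chromosome
            cursors[scaffold] += int(5 * fc.intergenic_mean)
        family = parse_family(fc.name)
        for i in range(fc.gene_count):
            if fc.gene_length_cv == 0:
                length = int(round(fc.gene_length_mean))
            else:
                draw = rng.normal(fc.gene_length_mean, fc.gene_length_cv * fc.gene_length_mean)
                length = max(100, int(round(draw)))
            strand = Strand.PLUS if rng.random() < 0.5 else Strand.MINUS
            start = cursors[scaffold]
            end = start + length
            if end > config.chromosome_length - margin:
                raise ValueError(
                    f"cluster {fc.name} does not fit on {scaffold}: needs "
                    f"chromosome length >= {end + margin}"
                )
            span = GenomicInterval(scaffold, start, end, strand)
            genes.append(
                GeneAnnotation(
                    gene_id=f"{fc.name}{i + 1}",
                    family=family,
                    span=span,
                    exons=_gene_exons(span, fc.exons_per_gene),
                    completeness="complete",
                    source="manual",
                )
            )
            gap = 1 + int(round(rng.exponential(fc.intergenic_mean)))
            cursors[scaffold] = end + gap
    annotation = AnnotationSet(
        genes, species="synthetic", assembly_id=f"sim-truth-{config.seed}", source="manual"
    )
    return TruthSet(assembly=AssemblyIndex(chroms), annotation=annotation, config=config)


@dataclass(frozen=True)
class FragmentedAssembly:
    assembly: AssemblyIndex
    annotation: AnnotationSet
    breakpoints: pd.DataFrame
    contig_order: Dict[str, List[str]]  # truth chromosome -> contigs, 5' to 3'


def fragment_assembly(
    truth: TruthSet, target_contig_N50: int, seed: int
) -> FragmentedAssembly:
    """Cut the truth chromosomes at uniform random breakpoints until the
    realised contig N50 falls within [0.5x, 2x] of the target. Genes split
    by a breakpoint are lifted as partial fragments; the longest fragment
    is the designated primary; fragment lengths sum to the truth length.
    """
    chrom_lengths = dict(truth.assembly.scaffold_lengths)
    total = sum(chrom_lengths.values())
    if target_contig_N50 < 1 or target_contig_N50 > max(chrom_lengths.values()):
        raise ValueError(
            f"target contig N50 {target_contig_N50} infeasible for chromosomes "
            f"of length <= {max(chrom_lengths.values())}"
        )
    rng = _rng(seed, "fragment")
    names = sorted(chrom_lengths)
    offsets = np.cumsum([0] + [chrom_lengths[n] for n in names])

    from .contiguity import assembly_n50

    n_breaks = max(0, int(round(total / target_contig_N50)) - len(names))
    breaks_by_chrom: Dict[str, List[int]] = {}
    for _ in range(60):
        positions = np.sort(rng.integers(1, total, size=n_breaks)) if n_breaks else np.array([], dtype=int)
        trial: Dict[str, List[int]] = {n: [] for n in names}
        for p in positions:
            idx = int(np.searchsorted(offsets, p, side="right")) - 1
            local = int(p - offsets[idx])
            if 0 < local < chrom_lengths[names[idx]]:
                trial[names[idx]].append(local)
        lengths: List[int] = []
        for n in names:
            cuts = sorted(set(trial[n]))
            edges = [0] + cuts + [chrom_lengths[n]]
            lengths.extend(b - a for a, b in zip(edges, edges[1:]))
        n50, _ = assembly_n50(lengths)
        if 0.5 * target_contig_N50 <= n50 <= 2.0 * target_contig_N50:
            breaks_by_chrom = {n: sorted(set(trial[n])) for n in names}
            break
        if n50 > 2.0 * target_contig_N50:
            n_breaks = max(n_breaks + 1, int(n_breaks * 1.3))
        else:
            n_breaks = max(0, min(n_breaks - 1, int(n_breaks * 0.7)))
    else:
        raise ValueError(
            f"could not realise contig N50 near {target_contig_N50} within iteration budget"
        )

    contig_lengths: Dict[str, int] = {}
    contig_order: Dict[str, List[str]] = {}
    contig_offsets: Dict[str, List[Tuple[int, int, str]]] = {}
    bp_rows = []
    for n in names:
        cuts = breaks_by_chrom.get(n, [])
        edges = [0] + cuts + [chrom_lengths[n]]
        contig_order[n] = []
        contig_offsets[n] = []
        for j, (a, b) in enumerate(zip(edges, edges[1:]), start=1):
            cname = f"{n}_c{j:04d}"
            contig_lengths[cname] = b - a
            contig_order[n].append(cname)
            contig_offsets[n].append((a, b, cname))
        for c in cuts:
            bp_rows.append({"chromosome": n, "position": c})

    genes: List[GeneAnnotation] = []
    for g in truth.annotation:
        pieces = []
        for a, b, cname in contig_offsets[g.scaffold]:
            lo = max(g.span.start, a)
            hi = min(g.span.end, b)
            if lo < hi:
                pieces.append((cname, a, lo, hi))
        if len(pieces) == 1:
            cname, a, lo, hi = pieces[0]
            span = GenomicInterval(cname, lo - a, hi - a, g.span.strand)
            exons = tuple(
                GenomicInterval(cname, e.start - a, e.end - a, e.strand) for e in g.exons
            )
            genes.append(g.with_(span=span, exons=exons))
        else:
            longest = max(range(len(pieces)), key=lambda i: pieces[i][3] - pieces[i][2])
            for k, (cname, a, lo, hi) in enumerate(pieces):
                span = GenomicInterval(cname, lo - a, hi - a, g.span.strand)
                exons = []
                for e in g.exons:
                    elo, ehi = max(e.start, lo), min(e.end, hi)
                    if elo < ehi:
                        exons.append(GenomicInterval(cname, elo - a, ehi - a, e.strand))
                genes.append(
                    g.with_(
                        gene_id=f"{g.gene_id}.f{k + 1}",
                        span=span,
                        exons=tuple(exons),
                        completeness="partial",
                        parent_id=g.gene_id,
                        is_primary=(k == longest),
                        fragment_count=len(pieces),
                    )
                )
    annotation = AnnotationSet(
        genes,
        species=truth.annotation.species,
        assembly_id=f"{truth.annotation.assembly_id}-frag",
        source="manual",
    )
    return FragmentedAssembly(
        assembly=AssemblyIndex(contig_lengths),
        annotation=annotation,
        breakpoints=pd.DataFrame(bp_rows, columns=["chromosome", "position"]),
        contig_order=contig_order,
    )


@dataclass(frozen=True)
class ScaffoldedAssembly:
    assembly: AssemblyIndex
    annotation: AnnotationSet
    layout: pd.DataFrame  # scaffold, contig, offset, inverted


def scaffold_with_errors(
    frag: FragmentedAssembly,
    inversion_rate: float,
    misjoin_rate: float,
    seed: int,
) -> ScaffoldedAssembly:
    """Re-join contigs into scaffolds, one per truth chromosome, in truth
    order. At each join the incoming contig is inverted with probability
    ``inversion_rate`` (flipping the strand of its genes) and, with
    probability ``misjoin_rate``, a contig from the tail of another
    chromosome is spliced in first. Contigs are joined without gaps, so an
    error-free scaffolding run restores truth coordinates exactly and
    re-merges gene fragments. Gene content is conserved overall.
    """
    rng = _rng(seed, "scaffold")
    contig_len = frag.assembly.scaffold_lengths
    queues: Dict[str, List[str]] = {c: list(v) for c, v in frag.contig_order.items()}
    chrom_names = sorted(queues)

    placements: List[Tuple[str, str, int, bool]] = []  # contig, scaffold, offset, inverted
    scaffold_lengths: Dict[str, int] = {}
    for chrom in chrom_names:
        if not queues[chrom]:
            continue
        sname = f"scaf_{chrom}"
        offset = 0

        def _place(cname: str, inverted: bool) -> None:
            nonlocal offset
            placements.append((cname, sname, offset, inverted))
            offset += contig_len[cname]

        _place(queues[chrom].pop(0), False)  # first contig anchors the scaffold
        while queues[chrom]:
            nxt = queues[chrom].pop(0)
            if rng.random() < misjoin_rate:
                donors = [c for c in chrom_names if c != chrom and queues[c]]
                if donors:
                    # swap: the donor's next contig lands here and the
                    # scheduled contig migrates to the donor's scaffold
                    donor = donors[int(rng.integers(len(donors)))]
                    nxt, queues[donor][0] = queues[donor][0], nxt
            _place(nxt, rng.random() < inversion_rate)
        scaffold_lengths[sname] = offset

    where: Dict[str, Tuple[str, int, bool]] = {
        c: (s, off, inv) for c, s, off, inv in placements
    }

    def lift(iv: GenomicInterval) -> GenomicInterval:
        sname, off, inv = where[iv.scaffold]
        clen = contig_len[iv.scaffold]
        if inv:
            return GenomicInterval(
                sname, off + clen - iv.end, off + clen - iv.start, iv.strand.flipped()
            )
        return GenomicInterval(sname, off + iv.start, off + iv.end, iv.strand)

    lifted: List[GeneAnnotation] = []
    by_parent: Dict[str, List[GeneAnnotation]] = {}
    for g in frag.annotation:
        span = lift(g.span)
        exons = tuple(sorted((lift(e) for e in g.exons), key=lambda e: e.start))
        g2 = g.with_(span=span, exons=exons)
        if g.parent_id is None:
            lifted.append(g2)
        else:
            by_parent.setdefault(g.parent_id, []).append(g2)

    # fragments that land back adjacent, in one orientation, fuse again
    for parent, frags in by_parent.items():
        frags.sort(key=lambda g: g.span.start)
        same_scaffold = len({g.scaffold for g in frags}) == 1
        same_strand = len({g.span.strand for g in frags}) == 1
        contiguous = all(
            a.span.end == b.span.start for a, b in zip(frags, frags[1:])
        )
        if same_scaffold and same_strand and contiguous and len(frags) == frags[0].fragment_count:
            span = GenomicInterval(
                frags[0].scaffold,
                frags[0].span.start,
                frags[-1].span.end,
                frags[0].span.strand,
            )
            exons = _union_intervals([e for g in frags for e in g.exons])
            lifted.append(
                frags[0].with_(
                    gene_id=parent,
                    span=span,
                    exons=exons,
                    completeness="complete",
                    parent_id=None,
                    is_primary=True,
                    fragment_count=1,
                )
            )
        else:
            lifted.extend(frags)

    annotation = AnnotationSet(
        sorted(lifted, key=lambda g: (g.scaffold, g.span.start, g.gene_id)),
        species=frag.annotation.species,
        assembly_id=f"{frag.annotation.assembly_id}-scaf",
        source="manual",
    )
    layout = pd.DataFrame(
        placements, columns=["contig", "scaffold", "offset", "inverted"]
    )
    return ScaffoldedAssembly(
        assembly=AssemblyIndex(scaffold_lengths), annotation=annotation, layout=layout
    )


def degrade_annotation(
    truth_annotation: AnnotationSet,
    miss_rate: float,
    overlap_beta: Optional[Tuple[float, float]],
    seed: int,
    max_models: int = 3,
    split_prob: float = 0.3,
) -> AnnotationSet:
    """Emulate an automated annotation of a known truth set.

    Each gene is independently dropped with probability ``miss_rate``;
    otherwise it is replaced by a model covering a Beta(a, b)-distributed
    fraction of its span, anchored at a uniformly chosen end, and with
    probability ``split_prob`` split into 2..``max_models`` abutting models
    (fragmented gene models, coverage unchanged). ``overlap_beta=None``
    means full coverage (the Beta distribution degenerate at 1). The
    expected mean overlap of retained genes is a/(a+b).
    """
    if not (0.0 <= miss_rate <= 1.0):
        raise ValueError(f"miss_rate {miss_rate} outside [0, 1]")
    if overlap_beta is not None and (overlap_beta[0] <= 0 or overlap_beta[1] <= 0):
        raise ValueError(f"invalid Beta parameters {overlap_beta}")
    models: List[GeneAnnotation] = []
    for i, g in enumerate(sorted(truth_annotation, key=lambda g: g.gene_id)):
        # independent substream per gene: toggling the split option must not
        # perturb the miss/coverage draws of later genes
        rng = np.random.default_rng([int(seed), _STAGE_IDS["degrade"], i])
        if rng.random() < miss_rate:
            continue
        frac = 1.0 if overlap_beta is None else float(rng.beta(*overlap_beta))
        cov = int(round(frac * g.span.length))
        if cov < 1:
            continue
        anchor_left = rng.random() < 0.5
        if anchor_left:
            lo, hi = g.span.start, g.span.start + cov
        else:
            lo, hi = g.span.end - cov, g.span.end
        pieces = [(lo, hi)]
        if cov >= max_models >= 2 and rng.random() < split_prob:
            k = int(rng.integers(2, max_models + 1))
            cuts = sorted(rng.choice(np.arange(lo + 1, hi), size=k - 1, replace=False))
            edges = [lo] + [int(c) for c in cuts] + [hi]
            pieces = list(zip(edges, edges[1:]))
        for j, (a, b) in enumerate(pieces, start=1):
            suffix = f"_m{j}" if len(pieces) > 1 else ""
            models.append(
                GeneAnnotation(
                    gene_id=f"auto_{g.gene_id}{suffix}",
                    family=g.family,
                    span=GenomicInterval(g.scaffold, a, b, g.span.strand),
                    source="automated",
                )
            )
    return AnnotationSet(
        models,
        species=truth_annotation.species,
        assembly_id=truth_annotation.assembly_id,
        source="automated",
    )
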