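"""Gene-set contiguity statistics and fragmentation reports.

The central statistic is the gene-set L50/L90: the minimum number of
scaffolds that together carry 50% / 90% of a curated gene set. Intact
clustered families (MHC, LRC, TCR loci) give small values; a family
scattered over many short scaffolds gives large ones. Scaffolds are
ranked by gene count — the greedy order is provably optimal for the
"fewest scaffolds covering a gene quota" objective — with ties broken by
scaffold id, ascending, for determinism.

Classic assembly N50/L50 over scaffold or contig lengths is included so
both axes of the quality-vs-fragmentation relationship come from one
module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, List, Optional, Sequence, Tuple, Union

import pandas as pd

from .model import AnnotationSet, AssemblyIndex, Family, GeneAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "gene_set_L",
    "assembly_n50",
    "orphan_scaffold_count",
    "cluster_report",
    "scaffold_length_quantile",
    "ClusterReport",
    "ContiguityReport",
    "contiguity_report",
]

LENGTH_THRESHOLDS: Tuple[int, ...] = (10_000, 15_000, 100_000)


def _as_fraction(fraction: Union[float, Fraction]) -> Fraction:
    """Exact threshold arithmetic: a float like 0.9 is taken at its printed
    decimal value (9/10), not its binary expansion, so 0.9 x 10 genes means
    exactly 9 genes."""
    if isinstance(fraction, Fraction):
        return fraction
    return Fraction(str(float(fraction)))


def _gene_counts(aset: AnnotationSet) -> Dict[str, int]:
    counts: Dict[str, int] = {}
    for g in aset.primary_genes():
        counts[g.scaffold] = counts.get(g.scaffold, 0) + 1
    return counts


def gene_set_L(aset: AnnotationSet, fraction: Union[float, Fraction]) -> int:
    """Smallest number of scaffolds that together carry ``fraction`` of the
    genes in ``aset`` (each gene counted once, on its span's scaffold;
    fragmented genes count via their primary fragment).
    """
    frac = _as_fraction(fraction)
    if not (0 < frac <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    counts = _gene_counts(aset)
    if not counts:
        raise ValueError("empty annotation set")
    n_total = sum(counts.values())
    need = frac * n_total
    cum = 0
    for k, (scaffold, c) in enumerate(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])), start=1
    ):
        cum += c
        if Fraction(cum) >= need:
            return k
    return len(counts)  # unreachable for fraction <= 1


def assembly_n50(lengths: Sequence[int]) -> Tuple[int, int]:
    """Classic (N50, L50) of a length multiset.

    N50 is the first length, in descending order, at which the cumulative
    sum reaches half the total; L50 is its rank.
    """
    if not len(lengths):
        raise ValueError("empty length list")
    ordered = sorted((int(x) for x in lengths), reverse=True)
    total = sum(ordered)
    cum = 0
    for rank, length in enumerate(ordered, start=1):
        cum += length
        if 2 * cum >= total:
            return length, rank
    raise AssertionError("unreachable")


def orphan_scaffold_count(aset: AnnotationSet, family: Family) -> int:
    """Scaffolds carrying exactly one gene of ``family`` — the orphan genes
    separated from their cluster by misassembly."""
    fam = aset.subset(family)
    if len(fam) == 0:
        logger.warning("family %s absent from set; orphan count 0", family.value)
        return 0
    counts = _gene_counts(fam)
    return sum(1 for c in counts.values() if c == 1)


@dataclass(frozen=True)
class ScaffoldClusterRow:
    scaffold: str
    gene_count: int
    cluster_start: int
    cluster_end: int
    max_intergene_gap: int
    scaffold_length: int


@dataclass(frozen=True)
class ClusterReport:
    family: str
    rows: Tuple[ScaffoldClusterRow, ...]
    pct_top_scaffold: float
    pct_scaffolds_below: Dict[int, float]
    orphan_scaffolds: int
    interleaved_with: Tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(vars(r) for r in self.rows)


def _interleaved(aset: AnnotationSet, fam_a: Family, fam_b: Family) -> bool:
    """Two families are interleaved on some shared scaffold if, reading
    genes in coordinate order, the family label switches more than once
    (i.e. the scaffold cannot be split into one block per family)."""
    scaffolds_a = {g.scaffold for g in aset.primary_genes() if g.family == fam_a}
    scaffolds_b = {g.scaffold for g in aset.primary_genes() if g.family == fam_b}
    for scaffold in scaffolds_a & scaffolds_b:
        order = [
            g.family
            for g in sorted(aset.on_scaffold(scaffold), key=lambda g: g.span.start)
            if g.family in (fam_a, fam_b) and g.is_primary
        ]
        switches = sum(1 for x, y in zip(order, order[1:]) if x != y)
        if switches > 1:
            return True
    return False


def cluster_report(
    aset: AnnotationSet,
    family: Family,
    assembly: AssemblyIndex,
    thresholds: Sequence[int] = LENGTH_THRESHOLDS,
) -> ClusterReport:
    """Per-scaffold cluster layout for one family plus the fragmentation
    percentages: share of family genes on the top scaffold, and share of
    family-bearing scaffolds below each length threshold."""
    fam = aset.subset(family)
    if len(fam) == 0:
        logger.warning("family %s absent from set", family.value)
        return ClusterReport(family.value, (), 0.0, {int(t): 0.0 for t in thresholds}, 0, ())
    for scaffold in fam.scaffolds:
        if scaffold not in assembly:
            raise KeyError(f"scaffold {scaffold!r} missing from assembly index")
    rows: List[ScaffoldClusterRow] = []
    for scaffold in sorted(fam.scaffolds):
        genes = sorted(
            (g for g in fam.on_scaffold(scaffold) if g.is_primary),
            key=lambda g: g.span.start,
        )
        if not genes:
            continue
        gaps = [b.span.start - a.span.end for a, b in zip(genes, genes[1:])]
        rows.append(
            ScaffoldClusterRow(
                scaffold=scaffold,
                gene_count=len(genes),
                cluster_start=genes[0].span.start,
                cluster_end=max(g.span.end for g in genes),
                max_intergene_gap=max(gaps) if gaps else 0,
                scaffold_length=assembly.length_of(scaffold),
            )
        )
    n_genes = sum(r.gene_count for r in rows)
    top = max(r.gene_count for r in rows)
    pct_below = {
        int(t): 100.0 * sum(1 for r in rows if r.scaffold_length < t) / len(rows)
        for t in thresholds
    }
    partner_families = [f for f in aset.families() if f != family]
    interleaved = tuple(
        f.value for f in partner_families if _interleaved(aset, family, f)
    )
    return ClusterReport(
        family=family.value,
        rows=tuple(sorted(rows, key=lambda r: (-r.gene_count, r.scaffold))),
        pct_top_scaffold=100.0 * top / n_genes,
        pct_scaffolds_below=pct_below,
        orphan_scaffolds=sum(1 for r in rows if r.gene_count == 1),
        interleaved_with=interleaved,
    )


def scaffold_length_quantile(
    aset: AnnotationSet, assembly: AssemblyIndex, p: float
) -> int:
    """Largest scaffold length L such that at least fraction ``p`` of genes
    lie on scaffolds of length >= L (gene-weighted)."""
    if not (0 < p < 1):
        raise ValueError(f"p must be in (0, 1), got {p}")
    genes = aset.primary_genes()
    if not genes:
        raise ValueError("empty annotation set")
    lengths = sorted((assembly.length_of(g.scaffold) for g in genes), reverse=True)
    need = _as_fraction(p) * len(lengths)
    k = 0
    cum = 0
    while Fraction(cum) < need:
        cum += 1
        k += 1
    return lengths[k - 1]


@dataclass(frozen=True)
class ContiguityReport:
    """Gene-set L statistics plus per-family fragmentation breakdowns."""

    species: str
    n_genes: int
    gene_L50: int
    gene_L90: int
    gene_bearing_scaffolds: int
    pct_genes_complete: float
    length_quantiles: Dict[float, int]
    families: Dict[str, ClusterReport]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, rep in self.families.items():
            rows.append(
                {
                    "family": name,
                    "n_scaffolds": len(rep.rows),
                    "n_genes": sum(r.gene_count for r in rep.rows),
                    "orphan_scaffolds": rep.orphan_scaffolds,
                    "pct_top_scaffold": rep.pct_top_scaffold,
                    **{
                        f"pct_scaffolds_lt_{t}": v
                        for t, v in rep.pct_scaffolds_below.items()
                    },
                    "interleaved_with": ",".join(rep.interleaved_with),
                }
            )
        return pd.DataFrame(rows)


def contiguity_report(
    aset: AnnotationSet,
    assembly: AssemblyIndex,
    fractions: Tuple[float, float] = (0.5, 0.9),
    quantiles: Sequence[float] = (0.9,),
    thresholds: Sequence[int] = LENGTH_THRESHOLDS,
) -> ContiguityReport:
    """Full contiguity report for one curated set on one assembly."""
    primary = aset.primary_genes()
    n_complete = sum(1 for g in primary if g.completeness == "complete")
    n_known = sum(1 for g in primary if g.completeness != "unknown")
    return ContiguityReport(
        species=aset.species,
        n_genes=len(primary),
        gene_L50=gene_set_L(aset, fractions[0]),
        gene_L90=gene_set_L(aset, fractions[1]),
        gene_bearing_scaffolds=len({g.scaffold for g in primary}),
        pct_genes_complete=(100.0 * n_complete / n_known) if n_known else float("nan"),
        length_quantiles={
            float(q): scaffold_length_quantile(aset, assembly, q) for q in quantiles
        },
        families={
            f.value: cluster_report(aset, f, assembly, thresholds)
            for f in aset.families()
        },
    )
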