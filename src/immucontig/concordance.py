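"""Manual-vs-automated annotation concordance.

For each manually curated gene the statistic is the fraction of its bases
covered by the union of all automated gene models on the same scaffold
(the curated gene length is the denominator; 0 means the gene is entirely
absent from the automated annotation). Genes are then binned into deciles
and flagged:

* ``correct``       — overlap >= 90%
* ``poor``          — overlap <= 10% (includes missing)
* ``missing``       — overlap == 0
* ``not_accurate``  — overlap <= 80%

The exon-level variant compares exon base sets instead of gene spans,
which credits pipelines that recover individual V segments or domain
exons as exons of some other model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .model import AnnotationSet, Family, GeneAnnotation, GenomicInterval, Strand

__all__ = [
    "BIN_LABELS",
    "OverlapRecord",
    "FamilySummary",
    "ConcordanceSummary",
    "gene_overlap_fraction",
    "exon_overlap_fraction",
    "classify_overlap",
    "summarize_concordance",
]

#: Decile bins: "0" holds exactly-zero overlaps; the rest are half-open
#: percentage intervals (0,10], (10,20], ..., (90,100].
BIN_LABELS: Tuple[str, ...] = ("0",) + tuple(
    f"({10 * k},{10 * (k + 1)}]" for k in range(10)
)


def _covered_length(target: GenomicInterval, pieces: Sequence[GenomicInterval]) -> int:
    """Bases of ``target`` covered by the union of ``pieces`` (same scaffold)."""
    clipped = []
    for p in pieces:
        lo = max(p.start, target.start)
        hi = min(p.end, target.end)
        if lo < hi:
            clipped.append((lo, hi))
    clipped.sort()
    covered = 0
    cur_lo: Optional[int] = None
    cur_hi = 0
    for lo, hi in clipped:
        if cur_lo is None or lo > cur_hi:
            if cur_lo is not None:
                covered += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    if cur_lo is not None:
        covered += cur_hi - cur_lo
    return covered


def _strand_ok(a: Strand, b: Strand, stranded: bool) -> bool:
    if not stranded:
        return True
    if Strand.UNKNOWN in (a, b):
        return True
    return a == b


def gene_overlap_fraction(
    gene: GeneAnnotation, automated: AnnotationSet, stranded: bool = False
) -> float:
    """Fraction of the curated gene's span covered by automated gene spans.

    Coverage accumulates over *all* intersecting automated models (automated
    pipelines routinely fragment one gene into several models), and the
    comparison is strand-agnostic unless ``stranded`` is set.
    """
    spans = [
        g.span
        for g in automated.on_scaffold(gene.scaffold)
        if _strand_ok(gene.span.strand, g.span.strand, stranded)
    ]
    if not spans:
        return 0.0
    return _covered_length(gene.span, spans) / gene.span.length


def exon_overlap_fraction(
    gene: GeneAnnotation, automated: AnnotationSet, stranded: bool = False
) -> float:
    """Fraction of the curated gene's exon bases covered by automated exon
    bases on the same scaffold.

    Either side falls back to its gene span when it carries no exon
    structure, so a span-only automated model still counts at exon level.
    """
    manual_exons = gene.exons if gene.exons else (gene.span,)
    auto_pieces: List[GenomicInterval] = []
    for g in automated.on_scaffold(gene.scaffold):
        if not _strand_ok(gene.span.strand, g.span.strand, stranded):
            continue
        auto_pieces.extend(g.exons if g.exons else (g.span,))
    denom = sum(e.length for e in manual_exons)
    if not auto_pieces or denom == 0:
        return 0.0
    covered = sum(_covered_length(e, auto_pieces) for e in manual_exons)
    return covered / denom


def classify_overlap(fraction: float) -> Tuple[str, Tuple[str, ...]]:
    """Assign the decile bin and threshold flags for one overlap fraction."""
    if not (0.0 <= fraction <= 1.0):
        raise ValueError(f"overlap fraction {fraction} outside [0, 1]")
    if fraction == 0.0:
        bin_label = "0"
    else:
        pct = 100.0 * fraction
        k = 0
        while 10 * (k + 1) < pct - 1e-9:
            k += 1
        k = min(k, 9)
        bin_label = f"({10 * k},{10 * (k + 1)}]"
    flags: List[str] = []
    if fraction >= 0.90:
        flags.append("correct")
    if fraction <= 0.10:
        flags.append("poor")
    if fraction == 0.0:
        flags.append("missing")
    if fraction <= 0.80:
        flags.append("not_accurate")
    return bin_label, tuple(flags)


@dataclass(frozen=True)
class OverlapRecord:
    gene_id: str
    family: Family
    gene_overlap: float
    exon_overlap: Optional[float]
    bin: str
    flags: Tuple[str, ...]


@dataclass(frozen=True)
class FamilySummary:
    family: str
    n: int
    histogram: Dict[str, int]
    pct_correct: float
    pct_poor: float
    pct_missing: float
    pct_not_accurate: float


@dataclass(frozen=True)
class ConcordanceSummary:
    """Per-family and total concordance statistics at gene or exon level.

    ``pct_poor`` uses the inclusive reading (<=10% includes 0%);
    ``pct_missing`` is reported separately so the exclusive reading is
    ``pct_poor - pct_missing``.
    """

    level: str
    species: str
    records: Tuple[OverlapRecord, ...]
    families: Tuple[FamilySummary, ...]
    total: FamilySummary

    def to_frame(self) -> pd.DataFrame:
        rows = [vars(f) | {"histogram": dict(f.histogram)} for f in self.families]
        rows.append(vars(self.total) | {"histogram": dict(self.total.histogram)})
        return pd.DataFrame(rows)

    def records_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": r.gene_id,
                "family": r.family.value,
                "gene_overlap": r.gene_overlap,
                "exon_overlap": r.exon_overlap,
                "bin": r.bin,
                "flags": ",".join(r.flags),
            }
            for r in self.records
        )


def _summary_for(label: str, records: Sequence[OverlapRecord], level: str) -> FamilySummary:
    n = len(records)
    hist = {b: 0 for b in BIN_LABELS}
    n_correct = n_poor = n_missing = n_notacc = 0
    for r in records:
        f = r.exon_overlap if (level == "exon" and r.exon_overlap is not None) else r.gene_overlap
        b, flags = classify_overlap(f)
        hist[b] += 1
        n_correct += "correct" in flags
        n_poor += "poor" in flags
        n_missing += "missing" in flags
        n_notacc += "not_accurate" in flags
    pct = lambda c: (100.0 * c / n) if n else 0.0
    return FamilySummary(
        family=label,
        n=n,
        histogram=hist,
        pct_correct=pct(n_correct),
        pct_poor=pct(n_poor),
        pct_missing=pct(n_missing),
        pct_not_accurate=pct(n_notacc),
    )


def summarize_concordance(
    manual: AnnotationSet,
    automated: AnnotationSet,
    level: str = "gene",
    stranded: bool = False,
) -> ConcordanceSummary:
    """Score every curated gene against the automated set and aggregate.

    Both sets must refer to the same assembly: comparing coordinates across
    assemblies is meaningless.
    """
    if level not in ("gene", "exon"):
        raise ValueError(f"level must be 'gene' or 'exon', not {level!r}")
    if manual.assembly_id and automated.assembly_id and manual.assembly_id != automated.assembly_id:
        raise ValueError(
            f"assembly mismatch: manual={manual.assembly_id!r} "
            f"automated={automated.assembly_id!r}"
        )
    records: List[OverlapRecord] = []
    for gene in sorted(manual, key=lambda g: g.gene_id):
        go = gene_overlap_fraction(gene, automated, stranded=stranded)
        eo = exon_overlap_fraction(gene, automated, stranded=stranded)
        frac = eo if level == "exon" else go
        b, flags = classify_overlap(frac)
        records.append(
            OverlapRecord(
                gene_id=gene.gene_id,
                family=gene.family,
                gene_overlap=go,
                exon_overlap=eo,
                bin=b,
                flags=flags,
            )
        )
    fam_order = [f for f in Family if any(r.family == f for r in records)]
    families = tuple(
        _summary_for(f.value, [r for r in records if r.family == f], level)
        for f in fam_order
    )
    total = _summary_for("total", records, level)
    return ConcordanceSummary(
        level=level,
        species=manual.species,
        records=tuple(records),
        families=families,
        total=total,
    )
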