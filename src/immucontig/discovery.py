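"""Post-processing of homology-search hits into candidate gene models.

The curation rules implemented here mirror manual annotation practice for
complex immune families: a permissive e-value filter (nothing potentially
real is discarded at the search stage), merging of overlapping hits into
domain calls, chaining of nearby domains (e.g. IGSF domains within 5 kbp
belong to one LRC gene), validation of V segments by a downstream
recombination signal sequence, a retention gate on top database hits, and
positional 5'-to-3' naming of duplicated genes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .model import Family, GenomicInterval, HomologyHit, Strand

logger = logging.getLogger(__name__)

__all__ = [
    "DomainCall",
    "GeneModelCandidate",
    "DEFAULT_LABEL_MAP",
    "DEFAULT_RETENTION_LABELS",
    "filter_hits",
    "merge_hits_to_domains",
    "chain_domains_to_genes",
    "pair_rss_to_v_segments",
    "apply_retention_gate",
    "assign_gene_names",
]

#: Pfam accessions to the domain vocabulary used for chaining.
DEFAULT_LABEL_MAP: Dict[str, str] = {"PF00047": "IGSF", "PF00059": "CLEC"}

#: Top-hit labels that admit an NK receptor candidate.
DEFAULT_RETENTION_LABELS: Set[str] = {
    "NK-swissprot",
    "NK-marsupial",
    "PF00047",
    "PF00059",
}


@dataclass(frozen=True)
class DomainCall:
    """A merged run of homology hits on one scaffold and strand."""

    scaffold: str
    interval: GenomicInterval
    domain_label: str
    supporting_hits: Tuple[str, ...]
    best_e_value: float


@dataclass(frozen=True)
class GeneModelCandidate:
    """A chained candidate gene model awaiting curation decisions."""

    name: str
    family: Family
    scaffold: str
    strand: Strand
    exons: Tuple[DomainCall, ...]
    span: GenomicInterval
    rss_flanked: Optional[bool] = None  # None = not applicable
    retained: Optional[bool] = None
    rejection_reason: Optional[str] = None


def filter_hits(hits: Iterable[HomologyHit], e_max: float = 10.0) -> List[HomologyHit]:
    """Keep hits with e-value <= ``e_max`` (inclusive; the permissive
    threshold is meant to exclude nothing borderline). Removed hits are
    counted and logged, never silently dropped."""
    hits = list(hits)
    kept = [h for h in hits if h.e_value <= e_max]
    removed = len(hits) - len(kept)
    if removed:
        logger.info("filter_hits: removed %d of %d hits above e-value %g",
                    removed, len(hits), e_max)
    return kept


def merge_hits_to_domains(
    hits: Iterable[HomologyHit],
    label_map: Optional[Mapping[str, str]] = None,
) -> List[DomainCall]:
    """Union overlapping-or-abutting hits on the same scaffold and strand
    into domain calls (abutting means ``next.start == prev.end``; a 1-bp
    gap keeps two calls). Labels come from ``label_map`` applied to the
    hit's domain label or query id (Pfam accessions map to IGSF/CLEC by
    default, anything else passes through)."""
    lmap = dict(DEFAULT_LABEL_MAP)
    if label_map:
        lmap.update(label_map)

    def label_of(h: HomologyHit) -> str:
        raw = h.domain_label or h.query_id
        return lmap.get(raw, raw)

    keyed: Dict[Tuple[str, Strand, str], List[HomologyHit]] = {}
    for h in hits:
        keyed.setdefault((h.scaffold, h.interval.strand, label_of(h)), []).append(h)

    calls: List[DomainCall] = []
    for (scaffold, strand, label), group in keyed.items():
        group.sort(key=lambda h: (h.interval.start, h.interval.end))
        run: List[HomologyHit] = []
        run_end = -1
        for h in group:
            if run and h.interval.start <= run_end:
                run.append(h)
                run_end = max(run_end, h.interval.end)
            else:
                if run:
                    calls.append(_make_call(scaffold, strand, label, run))
                run = [h]
                run_end = h.interval.end
        if run:
            calls.append(_make_call(scaffold, strand, label, run))
    calls.sort(key=lambda c: (c.scaffold, c.interval.strand.value, c.interval.start))
    return calls


def _make_call(scaffold: str, strand: Strand, label: str, run: Sequence[HomologyHit]) -> DomainCall:
    start = min(h.interval.start for h in run)
    end = max(h.interval.end for h in run)
    return DomainCall(
        scaffold=scaffold,
        interval=GenomicInterval(scaffold, start, end, strand),
        domain_label=label,
        supporting_hits=tuple(h.query_id for h in run),
        best_e_value=min(h.e_value for h in run),
    )


def chain_domains_to_genes(
    domains: Iterable[DomainCall],
    max_gap: int = 5_000,
    family: Family = Family.LRC,
    strand_aware: bool = True,
) -> List[GeneModelCandidate]:
    """Chain consecutive domains on one scaffold (and strand, unless
    ``strand_aware`` is off) into multi-exon candidates whenever the
    inter-domain gap (``next.start - prev.end``) is within ``max_gap``.

    The default 5 kbp gap is the rule used for IGSF domains of LRC genes;
    chains are maximal: every internal gap <= max_gap and the gap to the
    next candidate > max_gap.
    """
    def key(d: DomainCall):
        strand = d.interval.strand if strand_aware else Strand.UNKNOWN
        return (d.scaffold, strand.value)

    grouped: Dict[Tuple[str, str], List[DomainCall]] = {}
    for d in domains:
        grouped.setdefault(key(d), []).append(d)

    candidates: List[GeneModelCandidate] = []
    for (scaffold, strand_val), group in sorted(grouped.items()):
        group.sort(key=lambda d: (d.interval.start, d.interval.end))
        chain: List[DomainCall] = []
        chain_end = -1  # running max end handles nested/overlapping domains
        for d in group:
            if chain and d.interval.start - chain_end <= max_gap:
                chain.append(d)
                chain_end = max(chain_end, d.interval.end)
            else:
                if chain:
                    candidates.append(_make_candidate(chain, family, scaffold))
                chain = [d]
                chain_end = d.interval.end
        if chain:
            candidates.append(_make_candidate(chain, family, scaffold))
    candidates.sort(key=lambda c: (c.scaffold, c.span.start, c.strand.value))
    return candidates


def _make_candidate(chain: Sequence[DomainCall], family: Family, scaffold: str) -> GeneModelCandidate:
    strand = chain[0].interval.strand
    span = GenomicInterval(
        scaffold,
        chain[0].interval.start,
        max(d.interval.end for d in chain),
        strand,
    )
    return GeneModelCandidate(
        name="",
        family=family,
        scaffold=scaffold,
        strand=strand,
        exons=tuple(chain),
        span=span,
    )


def pair_rss_to_v_segments(
    v_candidates: Iterable[GeneModelCandidate],
    rss_domains: Iterable[DomainCall],
    window: int = 60,
) -> List[GeneModelCandidate]:
    """Flag V-segment candidates whose 3' end is flanked by a recombination
    signal sequence on the same strand within ``window`` bp.

    The 3' end is strand-dependent: for a plus-strand segment the RSS must
    start at or downstream of the segment end; for minus strand, end at or
    upstream of the segment start. The default window of 60 bp comfortably
    contains the 28-39 bp heptamer-spacer-nonamer motif that abuts the
    segment.
    """
    rss_by_key: Dict[Tuple[str, Strand], List[DomainCall]] = {}
    for r in rss_domains:
        rss_by_key.setdefault((r.scaffold, r.interval.strand), []).append(r)

    out: List[GeneModelCandidate] = []
    for cand in v_candidates:
        flanked = False
        for r in rss_by_key.get((cand.scaffold, cand.strand), ()):
            if cand.strand is Strand.MINUS:
                gap = cand.span.start - r.interval.end
            else:
                gap = r.interval.start - cand.span.end
            if 0 <= gap <= window:
                flanked = True
                break
        out.append(replace(cand, rss_flanked=flanked))
    return out


def apply_retention_gate(
    candidate: GeneModelCandidate,
    tophit_table: Mapping[str, Set[str]],
    allow_labels: Optional[Set[str]] = None,
    candidate_id: Optional[str] = None,
) -> GeneModelCandidate:
    """Retain a candidate iff its top database hits intersect the allow
    list (by default: swissprot NK genes, marsupial-specific NK genes, or
    the Pfam IGSF/C-type-lectin domain models). The top-hit table is
    produced externally; this operation only applies the gate."""
    allow = DEFAULT_RETENTION_LABELS if allow_labels is None else allow_labels
    cid = candidate_id or candidate.name or f"{candidate.scaffold}:{candidate.span.start}-{candidate.span.end}"
    labels = tophit_table.get(cid)
    if labels is None:
        return replace(candidate, retained=False, rejection_reason="no top hit evidence")
    if set(labels) & allow:
        return replace(candidate, retained=True, rejection_reason=None)
    return replace(candidate, retained=False, rejection_reason="no qualifying top hit")


def assign_gene_names(
    candidates: Sequence[GeneModelCandidate],
    family: Family,
    prefix: str,
) -> List[GeneModelCandidate]:
    """Name duplicated genes by genomic position, 5' to 3' along the plus
    reference orientation of the locus: ``prefix1 .. prefixN`` in ascending
    start order. Ties on start break by end, then by input order, with a
    warning (identical spans are a curation smell)."""
    order = sorted(
        range(len(candidates)),
        key=lambda i: (candidates[i].span.start, candidates[i].span.end, i),
    )
    spans = [(candidates[i].span.start, candidates[i].span.end) for i in order]
    if len(set(spans)) < len(spans):
        warnings.warn("identical candidate spans; naming ties broken by input order")
    named = list(candidates)
    for rank, i in enumerate(order, start=1):
        named[i] = replace(candidates[i], name=f"{prefix}{rank}", family=family)
    return [named[i] for i in order]
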