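"""Core domain types shared by every stage of the pipeline.

All coordinates held in these types are **0-based, half-open** on the
forward reference orientation. External formats (annotation tables, GFF3,
BLAST tabular, HMMER tables) are converted at the I/O boundary; see
:mod:`immucontig.io`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

__all__ = [
    "Strand",
    "Family",
    "parse_family",
    "GenomicInterval",
    "GeneAnnotation",
    "AnnotationSet",
    "AssemblyIndex",
    "HomologyHit",
]


class Strand(str, Enum):
    PLUS = "+"
    MINUS = "-"
    UNKNOWN = "."

    @classmethod
    def parse(cls, value: object) -> "Strand":
        s = str(value).strip() if value is not None else "."
        if s in ("+", "1", "+1"):
            return cls.PLUS
        if s in ("-", "-1"):
            return cls.MINUS
        return cls.UNKNOWN

    def flipped(self) -> "Strand":
        if self is Strand.PLUS:
            return Strand.MINUS
        if self is Strand.MINUS:
            return Strand.PLUS
        return Strand.UNKNOWN


class Family(str, Enum):
    """Immune gene families/groups used for per-family reporting."""

    CYTOKINE = "cytokine"
    TLR = "TLR"
    MHC_I = "MHC_I"
    MHC_II = "MHC_II"
    MHC_III = "MHC_III"
    MHC_EXT_FRAMEWORK = "MHC_ext_framework"
    NKC = "NKC"
    LRC = "LRC"
    LRC_EXT = "LRC_ext"
    IG_C = "IG_C"
    IG_V = "IG_V"
    TCR_C = "TCR_C"
    TCR_V = "TCR_V"
    OTHER = "other"


def _norm(label: str) -> str:
    return "".join(ch for ch in label.lower() if ch.isalnum())


#: Synonym table mapping free-text family labels (as they appear in curated
#: spreadsheets) onto the enum. User-extensible via ``register_family_synonym``.
FAMILY_SYNONYMS: Dict[str, Family] = {}


def register_family_synonym(label: str, family: Family) -> None:
    FAMILY_SYNONYMS[_norm(label)] = family


for _label, _fam in [
    ("cytokine", Family.CYTOKINE),
    ("cytokines", Family.CYTOKINE),
    ("tlr", Family.TLR),
    ("toll-like receptor", Family.TLR),
    ("mhc i", Family.MHC_I),
    ("mhc class i", Family.MHC_I),
    ("mhc_i", Family.MHC_I),
    ("mhc ii", Family.MHC_II),
    ("mhc class ii", Family.MHC_II),
    ("mhc_ii", Family.MHC_II),
    ("mhc iii", Family.MHC_III),
    ("mhc class iii", Family.MHC_III),
    ("mhc_iii", Family.MHC_III),
    ("ext. mhc & framework genes", Family.MHC_EXT_FRAMEWORK),
    ("extended mhc and framework", Family.MHC_EXT_FRAMEWORK),
    ("mhc ext framework", Family.MHC_EXT_FRAMEWORK),
    ("mhc_ext_framework", Family.MHC_EXT_FRAMEWORK),
    ("nkc", Family.NKC),
    ("natural killer complex", Family.NKC),
    ("lrc", Family.LRC),
    ("leukocyte receptor complex", Family.LRC),
    ("extended lrc", Family.LRC_EXT),
    ("lrc ext", Family.LRC_EXT),
    ("lrc_ext", Family.LRC_EXT),
    ("ig constant", Family.IG_C),
    ("ig_c", Family.IG_C),
    ("ig variable", Family.IG_V),
    ("ig_v", Family.IG_V),
    ("tcr constant", Family.TCR_C),
    ("tcr_c", Family.TCR_C),
    ("tcr variable", Family.TCR_V),
    ("tcr_v", Family.TCR_V),
    ("other", Family.OTHER),
]:
    register_family_synonym(_label, _fam)


def parse_family(label: str) -> Family:
    """Map a free-text family label to the enum.

    Unknown labels fall back to ``Family.OTHER`` with a warning, so a
    curated table with an unexpected row label is never silently dropped.
    """
    fam = FAMILY_SYNONYMS.get(_norm(label))
    if fam is None:
        warnings.warn(f"unknown gene family label {label!r}; using 'other'")
        return Family.OTHER
    return fam


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval on a scaffold."""

    scaffold: str
    start: int
    end: int
    strand: Strand = Strand.UNKNOWN

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.scaffold}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.scaffold == other.scaffold
            and self.start < other.end
            and other.start < self.end
        )


def _exons_valid(span: GenomicInterval, exons: Sequence[GenomicInterval]) -> None:
    prev_end = None
    for ex in sorted(exons, key=lambda e: (e.start, e.end)):
        if ex.scaffold != span.scaffold or ex.start < span.start or ex.end > span.end:
            raise ValueError(f"exon {ex} not contained in gene span {span}")
        if prev_end is not None and ex.start < prev_end:
            raise ValueError("exons overlap within one gene")
        prev_end = ex.end


@dataclass(frozen=True)
class GeneAnnotation:
    """One curated or automated gene model, optionally with exon structure.

    ``parent_id``/``fragment_count`` track genes split across assembly
    breakpoints by the simulator: fragments carry their parent's id and the
    total number of sibling fragments, and exactly one fragment per parent
    is the designated primary (the longest) used for per-scaffold counting.
    """

    gene_id: str
    family: Family
    span: GenomicInterval
    exons: Tuple[GenomicInterval, ...] = ()
    completeness: str = "unknown"  # complete | partial | unknown
    source: str = "manual"  # manual | automated
    parent_id: Optional[str] = None
    is_primary: bool = True
    fragment_count: int = 1

    def __post_init__(self) -> None:
        if self.completeness not in ("complete", "partial", "unknown"):
            raise ValueError(f"bad completeness {self.completeness!r}")
        if self.source not in ("manual", "automated"):
            raise ValueError(f"bad source {self.source!r}")
        object.__setattr__(self, "exons", tuple(self.exons))
        _exons_valid(self.span, self.exons)

    @property
    def scaffold(self) -> str:
        return self.span.scaffold

    @property
    def length(self) -> int:
        return self.span.length

    def with_(self, **kw) -> "GeneAnnotation":
        return replace(self, **kw)


class AnnotationSet:
    """A named collection of gene annotations for one species/source.

    Gene ids are unique within a set; genes are indexed by scaffold for
    overlap queries.
    """

    def __init__(
        self,
        genes: Iterable[GeneAnnotation] = (),
        species: str = "",
        assembly_id: str = "",
        source: str = "manual",
    ) -> None:
        self.species = species
        self.assembly_id = assembly_id
        self.source = source
        self._genes: List[GeneAnnotation] = []
        self._by_id: Dict[str, GeneAnnotation] = {}
        self._index: Dict[str, List[GeneAnnotation]] = {}
        for g in genes:
            self.add(g)

    def add(self, gene: GeneAnnotation) -> None:
        if gene.gene_id in self._by_id:
            raise ValueError(f"duplicate gene_id {gene.gene_id!r}")
        self._genes.append(gene)
        self._by_id[gene.gene_id] = gene
        self._index.setdefault(gene.scaffold, []).append(gene)

    def __len__(self) -> int:
        return len(self._genes)

    def __iter__(self) -> Iterator[GeneAnnotation]:
        return iter(self._genes)

    def __getitem__(self, gene_id: str) -> GeneAnnotation:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    @property
    def genes(self) -> Tuple[GeneAnnotation, ...]:
        return tuple(self._genes)

    @property
    def scaffolds(self) -> Tuple[str, ...]:
        return tuple(self._index)

    def on_scaffold(self, scaffold: str) -> Tuple[GeneAnnotation, ...]:
        return tuple(self._index.get(scaffold, ()))

    def families(self) -> Tuple[Family, ...]:
        seen: List[Family] = []
        for g in self._genes:
            if g.family not in seen:
                seen.append(g.family)
        return tuple(seen)

    def subset(self, family: Family) -> "AnnotationSet":
        return AnnotationSet(
            (g for g in self._genes if g.family == family),
            species=self.species,
            assembly_id=self.assembly_id,
            source=self.source,
        )

    def primary_genes(self) -> Tuple[GeneAnnotation, ...]:
        """Genes counted once: unfragmented genes plus primary fragments."""
        return tuple(g for g in self._genes if g.is_primary)


class AssemblyIndex:
    """Scaffold (or contig) length table with derived contiguity metrics."""

    def __init__(self, scaffold_lengths: Dict[str, int]) -> None:
        if not scaffold_lengths:
            raise ValueError("empty assembly index")
        for name, length in scaffold_lengths.items():
            if int(length) < 1:
                raise ValueError(f"scaffold {name!r} has non-positive length {length}")
        self.scaffold_lengths: Dict[str, int] = {
            str(k): int(v) for k, v in scaffold_lengths.items()
        }

    def __len__(self) -> int:
        return len(self.scaffold_lengths)

    def __contains__(self, scaffold: str) -> bool:
        return scaffold in self.scaffold_lengths

    def length_of(self, scaffold: str) -> int:
        return self.scaffold_lengths[scaffold]

    @property
    def total_length(self) -> int:
        return sum(self.scaffold_lengths.values())

    @property
    def scaffold_count(self) -> int:
        return len(self.scaffold_lengths)

    @property
    def scaffold_N50(self) -> int:
        from .contiguity import assembly_n50

        return assembly_n50(list(self.scaffold_lengths.values()))[0]

    @property
    def scaffold_L50(self) -> int:
        from .contiguity import assembly_n50

        return assembly_n50(list(self.scaffold_lengths.values()))[1]


@dataclass(frozen=True)
class HomologyHit:
    """One similarity-search hit placed on the assembly."""

    query_id: str
    scaffold: str
    interval: GenomicInterval
    e_value: float
    bit_score: float
    hit_kind: str  # blast | hmmer_domain
    domain_label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError(f"negative e-value {self.e_value}")
        if self.hit_kind not in ("blast", "hmmer_domain"):
            raise ValueError(f"bad hit_kind {self.hit_kind!r}")
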