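"""Readers and writers for the external formats the pipeline touches.

Conventions handled here, once:

* curated annotation tables (TSV/CSV) and GFF3 are **1-based inclusive**;
* BED is **0-based half-open**;
* BLAST tabular subject coordinates are 1-based inclusive and reversed on
  minus-strand hits; HMMER ``domtblout`` envelope coordinates are 1-based
  inclusive.

Everything is converted to the internal 0-based half-open convention of
:mod:`immucontig.model` on the way in and back on the way out.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import pandas as pd

from .model import (
    AnnotationSet,
    AssemblyIndex,
    Family,
    GeneAnnotation,
    GenomicInterval,
    HomologyHit,
    Strand,
    parse_family,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationFormatError",
    "AnnotationRecordError",
    "DEFAULT_COLUMNS",
    "read_annotation_table",
    "read_gff3",
    "read_fasta_index",
    "read_blast_tab",
    "read_domtblout",
    "write_annotation",
    "write_fasta_stub",
]


class AnnotationFormatError(ValueError):
    """The file as a whole does not match the expected layout."""


class AnnotationRecordError(ValueError):
    """A single record is invalid; the message names the row."""


#: Default column mapping for curated annotation tables. Keys are logical
#: fields, values are the header names looked up in the file. Override any
#: entry via ``column_map`` to accept other spreadsheet layouts.
DEFAULT_COLUMNS: Dict[str, str] = {
    "gene_id": "gene_id",
    "family": "family",
    "scaffold": "scaffold",
    "start": "start",
    "end": "end",
    "strand": "strand",
    "completeness": "completeness",
    "species": "species",
    "exons": "exons",
}

_MANDATORY = ("gene_id", "family", "scaffold", "start", "end")


def _read_table(path: Union[str, Path]) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, dtype=str, comment="#")


def _parse_exons(spec: str, scaffold: str, strand: Strand) -> Tuple[GenomicInterval, ...]:
    """Parse an exon list written as ``start-end;start-end`` (1-based inclusive)."""
    exons = []
    for part in str(spec).split(";"):
        part = part.strip()
        if not part:
            continue
        lo, hi = part.split("-")
        exons.append(GenomicInterval(scaffold, int(lo) - 1, int(hi), strand))
    return tuple(sorted(exons, key=lambda e: e.start))


def read_annotation_table(
    path: Union[str, Path],
    species_filter: Optional[str] = None,
    column_map: Optional[Dict[str, str]] = None,
    source: str = "manual",
    assembly_id: str = "",
) -> AnnotationSet:
    """Read a curated annotation table (TSV or CSV, 1-based inclusive).

    Mandatory columns: gene id, family, scaffold, start, end. Optional:
    strand, completeness, species, exons (``start-end;...``). ``column_map``
    overrides the default header names so differently laid out spreadsheets
    can be ingested without editing the file.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = _read_table(path)
    for logical in _MANDATORY:
        if cols[logical] not in df.columns:
            raise AnnotationFormatError(
                f"{path}: missing mandatory column {cols[logical]!r} (for {logical})"
            )
    if species_filter is not None and cols["species"] in df.columns:
        df = df[df[cols["species"]].astype(str) == species_filter]

    species = species_filter or ""
    if not species and cols["species"] in df.columns and len(df):
        uniq = df[cols["species"]].dropna().unique()
        if len(uniq) == 1:
            species = str(uniq[0])

    genes: List[GeneAnnotation] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        rec = dict(zip(df.columns, row))
        try:
            start = int(rec[cols["start"]])
            end = int(rec[cols["end"]])
        except (TypeError, ValueError) as exc:
            raise AnnotationRecordError(f"{path} row {row_no}: non-integer coordinate") from exc
        if start > end:
            raise AnnotationRecordError(
                f"{path} row {row_no}: start {start} > end {end}"
            )
        strand = Strand.parse(rec.get(cols["strand"], "."))
        scaffold = str(rec[cols["scaffold"]])
        span = GenomicInterval(scaffold, start - 1, end, strand)
        exons: Tuple[GenomicInterval, ...] = ()
        raw_exons = rec.get(cols["exons"])
        if raw_exons is not None and not pd.isna(raw_exons):
            exons = _parse_exons(raw_exons, scaffold, strand)
        completeness = str(rec.get(cols["completeness"], "unknown") or "unknown")
        if pd.isna(rec.get(cols["completeness"], "unknown")):
            completeness = "unknown"
        genes.append(
            GeneAnnotation(
                gene_id=str(rec[cols["gene_id"]]),
                family=parse_family(str(rec[cols["family"]])),
                span=span,
                exons=exons,
                completeness=completeness,
                source=source,
            )
        )
    return AnnotationSet(genes, species=species, assembly_id=assembly_id, source=source)


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(
    path: Union[str, Path],
    feature_policy: Sequence[str] = ("gene", "mRNA", "exon-union"),
    source: str = "automated",
    assembly_id: str = "",
    species: str = "",
) -> AnnotationSet:
    """Read automated annotations from GFF3.

    ``feature_policy`` names, in order of preference, which feature types
    constitute gene spans: ``gene`` features if any exist, else ``mRNA``,
    else the union of exon/CDS features grouped by their ``Parent``
    attribute. Exon children are attached to their parent gene; an exon
    whose Parent is unknown is kept as its own single-exon gene with a
    warning. Comment lines, CRLF endings and out-of-order features are
    tolerated (the file is loaded into an in-memory feature database).
    """
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
            force=True,
        )
    except Exception as exc:  # gffutils reports the offending line
        raise AnnotationFormatError(f"{path}: cannot parse GFF3: {exc}") from exc

    def _interval(f) -> GenomicInterval:
        if f.start > f.end:
            raise AnnotationRecordError(
                f"{path}: feature {f.id} has start {f.start} > end {f.end}"
            )
        return GenomicInterval(f.seqid, f.start - 1, f.end, Strand.parse(f.strand))

    def _exons_of(parent) -> Tuple[GenomicInterval, ...]:
        exons = [
            _interval(e)
            for e in db.children(parent, featuretype=("exon", "CDS"), order_by="start")
        ]
        # CDS may duplicate exon extents; union them
        return _union_intervals(exons)

    genes: List[GeneAnnotation] = []
    used_policy = None
    for policy in feature_policy:
        if policy in ("gene", "mRNA"):
            feats = list(db.features_of_type(policy, order_by=("seqid", "start")))
            if feats:
                used_policy = policy
                for f in feats:
                    genes.append(
                        GeneAnnotation(
                            gene_id=f.id,
                            family=Family.OTHER,
                            span=_interval(f),
                            exons=_exons_of(f),
                            source=source,
                        )
                    )
                break
        elif policy == "exon-union":
            groups: Dict[str, List[GenomicInterval]] = {}
            strands: Dict[str, Strand] = {}
            for f in db.features_of_type(("exon", "CDS"), order_by=("seqid", "start")):
                parent = (f.attributes.get("Parent") or [f.id or "orphan"])[0]
                groups.setdefault(parent, []).append(_interval(f))
                strands[parent] = Strand.parse(f.strand)
            if groups:
                used_policy = policy
                for parent, ivs in groups.items():
                    ivs = _union_intervals(ivs)
                    span = GenomicInterval(
                        ivs[0].scaffold, ivs[0].start, ivs[-1].end, strands[parent]
                    )
                    genes.append(
                        GeneAnnotation(
                            gene_id=parent,
                            family=Family.OTHER,
                            span=span,
                            exons=ivs,
                            source=source,
                        )
                    )
                break
    if used_policy is None:
        logger.info("%s: no features matching policy %s; empty set", path, feature_policy)

    # orphan exons when a gene/mRNA policy was used
    if used_policy in ("gene", "mRNA"):
        known = {g.gene_id for g in genes}
        for f in db.features_of_type("exon", order_by=("seqid", "start")):
            if _has_ancestor(db, f, used_policy):
                continue
            parent = (f.attributes.get("Parent") or ["?"])[0]
            warnings.warn(
                f"{path}: exon with unknown Parent {parent!r} kept as its own gene"
            )
            iv = _interval(f)
            gid = f.id or f"orphan_{iv.scaffold}_{iv.start}"
            if gid not in known:
                genes.append(
                    GeneAnnotation(gene_id=gid, family=Family.OTHER, span=iv,
                                   exons=(iv,), source=source)
                )
                known.add(gid)
    return AnnotationSet(genes, species=species, assembly_id=assembly_id, source=source)


def _has_ancestor(db, feature, featuretype: str) -> bool:
    try:
        return any(True for _ in db.parents(feature, featuretype=featuretype))
    except Exception:
        return False


def _union_intervals(ivs: Sequence[GenomicInterval]) -> Tuple[GenomicInterval, ...]:
    """Union same-scaffold intervals; overlapping or abutting runs merge."""
    out: List[GenomicInterval] = []
    for iv in sorted(ivs, key=lambda i: (i.scaffold, i.start, i.end)):
        if out and out[-1].scaffold == iv.scaffold and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.scaffold, out[-1].start, iv.end, out[-1].strand)
        else:
            out.append(iv)
    return tuple(out)


# ---------------------------------------------------------------------------
# Assembly indexes


def read_fasta_index(path: Union[str, Path]) -> AssemblyIndex:
    """Read scaffold lengths from a samtools ``.fai`` (5-column) or a
    two-column ``scaffold<TAB>length`` table."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] not in (2, 5):
        raise AnnotationFormatError(
            f"{path}: expected 2 (TSV) or 5 (.fai) columns, found {df.shape[1]}"
        )
    names = df[0].astype(str)
    if names.duplicated().any():
        dup = names[names.duplicated()].iloc[0]
        raise AnnotationFormatError(f"{path}: duplicate scaffold name {dup!r}")
    try:
        lengths = df[1].astype(int)
    except ValueError as exc:
        raise AnnotationFormatError(f"{path}: non-integer length column") from exc
    return AssemblyIndex(dict(zip(names, lengths)))


def write_fasta_stub(assembly: AssemblyIndex, path: Union[str, Path], line_width: int = 60) -> None:
    """Write a FASTA whose sequences are a fixed periodic ACGT pattern of
    the indexed lengths — placeholder sequence content so downstream
    format readers (faidx etc.) can be exercised; no biology implied."""
    with open(path, "w") as fh:
        for name in sorted(assembly.scaffold_lengths):
            length = assembly.length_of(name)
            fh.write(f">{name}\n")
            seq = ("ACGT" * (length // 4 + 1))[:length]
            for i in range(0, length, line_width):
                fh.write(seq[i : i + line_width] + "\n")


# ---------------------------------------------------------------------------
# Homology search output

_BLAST_COLS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_blast_tab(path: Union[str, Path]) -> List[HomologyHit]:
    """Read BLAST tabular output (``-outfmt 6``, 12 standard columns).

    Subject coordinates are 1-based inclusive; ``sstart > send`` marks a
    minus-strand hit and is normalised to a forward interval with
    ``strand='-'``.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] != len(_BLAST_COLS):
        raise AnnotationFormatError(
            f"{path}: expected {len(_BLAST_COLS)} columns, found {df.shape[1]}"
        )
    df.columns = _BLAST_COLS
    hits: List[HomologyHit] = []
    for row in df.itertuples(index=False):
        s, e = int(row.sstart), int(row.send)
        strand = Strand.PLUS if s <= e else Strand.MINUS
        lo, hi = (s, e) if s <= e else (e, s)
        if float(row.evalue) < 0:
            raise AnnotationRecordError(f"{path}: negative e-value {row.evalue}")
        hits.append(
            HomologyHit(
                query_id=str(row.qseqid),
                scaffold=str(row.sseqid),
                interval=GenomicInterval(str(row.sseqid), lo - 1, hi, strand),
                e_value=float(row.evalue),
                bit_score=float(row.bitscore),
                hit_kind="blast",
            )
        )
    return hits


def read_domtblout(path: Union[str, Path]) -> List[HomologyHit]:
    """Read a HMMER3 per-domain table (``--domtblout``).

    Envelope coordinates (columns 20-21, 1-based inclusive) place the
    domain on the target sequence; the independent e-value (column 13) and
    domain bit score (column 14) are kept.
    """
    hits: List[HomologyHit] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split(None, 22)
            if len(parts) < 22:
                raise AnnotationFormatError(
                    f"{path} line {line_no}: expected >=22 whitespace-separated fields"
                )
            target, query = parts[0], parts[3]
            query_acc = parts[4]
            e_value = float(parts[12])
            if e_value < 0:
                raise AnnotationRecordError(f"{path} line {line_no}: negative e-value")
            score = float(parts[13])
            env_from, env_to = int(parts[19]), int(parts[20])
            strand = Strand.PLUS
            if env_from > env_to:  # nhmmer-style reverse-strand envelope
                env_from, env_to = env_to, env_from
                strand = Strand.MINUS
            label = query_acc if query_acc not in ("-", "") else query
            label = label.split(".")[0]
            hits.append(
                HomologyHit(
                    query_id=query,
                    scaffold=target,
                    interval=GenomicInterval(target, env_from - 1, env_to, strand),
                    e_value=e_value,
                    bit_score=score,
                    hit_kind="hmmer_domain",
                    domain_label=label,
                )
            )
    return hits


# ---------------------------------------------------------------------------
# Writers


def write_annotation(aset: AnnotationSet, path: Union[str, Path], format: str = "gff3") -> None:
    """Write an annotation set as GFF3 (1-based inclusive), BED (0-based
    half-open) or the curated-table TSV dialect read by
    :func:`read_annotation_table`. GFF3/TSV round-trip exactly."""
    path = Path(path)
    if format == "gff3":
        lines = ["##gff-version 3"]
        for g in aset:
            attrs = f"ID={g.gene_id};family={g.family.value};completeness={g.completeness}"
            lines.append(
                "\t".join(
                    [g.scaffold, "immucontig", "gene", str(g.span.start + 1),
                     str(g.span.end), ".", g.span.strand.value, ".", attrs]
                )
            )
            for i, ex in enumerate(g.exons, start=1):
                lines.append(
                    "\t".join(
                        [ex.scaffold, "immucontig", "exon", str(ex.start + 1),
                         str(ex.end), ".", ex.strand.value, ".",
                         f"ID={g.gene_id}.exon{i};Parent={g.gene_id}"]
                    )
                )
    elif format == "bed":
        lines = []
        for g in aset:
            strand = g.span.strand.value if g.span.strand is not Strand.UNKNOWN else "."
            lines.append(
                "\t".join(
                    [g.scaffold, str(g.span.start), str(g.span.end), g.gene_id, "0", strand]
                )
            )
        if not lines:
            lines = ["#chrom\tstart\tend\tname\tscore\tstrand"]
    elif format == "tsv":
        header = "gene_id\tfamily\tscaffold\tstart\tend\tstrand\tcompleteness\texons"
        lines = [header]
        for g in aset:
            exons = ";".join(f"{e.start + 1}-{e.end}" for e in g.exons)
            lines.append(
                "\t".join(
                    [g.gene_id, g.family.value, g.scaffold, str(g.span.start + 1),
                     str(g.span.end), g.span.strand.value, g.completeness, exons]
                )
            )
    else:
        raise ValueError(f"unknown format {format!r}")
    path.write_text("\n".join(lines) + "\n")
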