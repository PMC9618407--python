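import pytest

from immucontig.model import (
    AnnotationSet,
    Family,
    GeneAnnotation,
    GenomicInterval,
    Strand,
)


def make_gene(
    gene_id,
    scaffold,
    start,
    end,
    family=Family.OTHER,
    strand=Strand.PLUS,
    exons=(),
    source="manual",
    **kw,
):
    span = GenomicInterval(scaffold, start, end, strand)
    exon_ivs = tuple(GenomicInterval(scaffold, a, b, strand) for a, b in exons)
    return GeneAnnotation(
        gene_id=gene_id, family=family, span=span, exons=exon_ivs, source=source, **kw
    )


def make_set(genes, source="manual", assembly_id="asm1", species="testopossum"):
    return AnnotationSet(genes, species=species, assembly_id=assembly_id, source=source)


@pytest.fixture
def two_family_set():
    return make_set(
        [
            make_gene("TLR1", "s1", 100, 5100, family=Family.TLR),
            make_gene("UA1", "s2", 200, 10200, family=Family.MHC_I),
        ]
    )
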