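"""Curate homology hits into named candidate gene models.

Simulates the post-search steps for an LRC-style locus: filter hits at
the permissive e-value 10, merge overlapping hits into IGSF domain calls,
chain domains within 5 kbp into multi-exon candidates, check RSS flanking
for a V segment, apply the top-hit retention gate, and name candidates
5' to 3'.
"""

from immucontig.discovery import (
    apply_retention_gate, assign_gene_names, chain_domains_to_genes,
    filter_hits, merge_hits_to_domains, pair_rss_to_v_segments,
)
from immucontig.model import Family, GenomicInterval, HomologyHit, Strand

def hit(start, end, e, label="PF00047", q="igsf_model"):
    return HomologyHit(query_id=q, scaffold="scaf1",
                       interval=GenomicInterval("scaf1", start, end, Strand.PLUS),
                       e_value=e, bit_score=55.0, hit_kind="hmmer_domain",
                       domain_label=label)

hits = [
    hit(10_000, 10_300, 1e-12),            # exon 1, two overlapping hits
    hit(10_150, 10_400, 1e-8),
    hit(13_000, 13_280, 1e-9),             # exon 2, 2.6 kbp downstream
    hit(30_000, 30_290, 1e-7),             # separate gene, 16 kbp away
    hit(50_000, 50_200, 25.0),             # above threshold, discarded
]

kept = filter_hits(hits, e_max=10)
domains = merge_hits_to_domains(kept)
print(f"{len(hits)} hits -> {len(kept)} after e-value filter -> {len(domains)} domain calls")

candidates = chain_domains_to_genes(domains, max_gap=5_000, family=Family.LRC)
candidates = assign_gene_names(candidates, Family.LRC, "LRC")
for c in candidates:
    print(f"  {c.name}: {c.scaffold}:{c.span.start}-{c.span.end} "
          f"({len(c.exons)} exon(s))")

gated = [apply_retention_gate(c, {"LRC1": {"PF00047"}, "LRC2": {"keratin"}},
                              candidate_id=c.name) for c in candidates]
for c in gated:
    verdict = "retained" if c.retained else f"rejected ({c.rejection_reason})"
    print(f"  {c.name}: {verdict}")

# an RSS 20 bp downstream validates a V-segment candidate
v = assign_gene_names(chain_domains_to_genes(
    merge_hits_to_domains([hit(70_000, 70_300, 1e-10, q="v_model")]),
    family=Family.IG_V), Family.IG_V, "IGHV")
rss = merge_hits_to_domains([hit(70_320, 70_355, 1e-4, label="RSS", q="rss_model")])
(flagged,) = pair_rss_to_v_segments(v, rss, window=60)
print(f"  {flagged.name}: RSS-flanked={flagged.rss_flanked}")
print("\nTwo nearby IGSF domains form one multi-exon gene; the retention gate")
print("drops candidates whose best database hits are not NK/IGSF/CLEC-like.")
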