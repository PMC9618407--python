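"""Homology-hit curation: filtering, domain merging, chaining, RSS
pairing, the retention gate and positional naming."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from immucontig.discovery import (
    DomainCall,
    apply_retention_gate,
    assign_gene_names,
    chain_domains_to_genes,
    filter_hits,
    merge_hits_to_domains,
    pair_rss_to_v_segments,
)
from immucontig.model import Family, GenomicInterval, HomologyHit, Strand


def hit(start, end, scaffold="s1", strand=Strand.PLUS, e=1e-5, label=None, q="q"):
    return HomologyHit(
        query_id=q,
        scaffold=scaffold,
        interval=GenomicInterval(scaffold, start, end, strand),
        e_value=e,
        bit_score=50.0,
        hit_kind="hmmer_domain",
        domain_label=label,
    )


def domain(start, end, scaffold="s1", strand=Strand.PLUS, label="IGSF"):
    return DomainCall(
        scaffold=scaffold,
        interval=GenomicInterval(scaffold, start, end, strand),
        domain_label=label,
        supporting_hits=("h",),
        best_e_value=1e-5,
    )


# ---------------------------------------------------------------------------
# filtering

def test_filter_threshold_inclusive():
    hits = [hit(0, 10, e=0.001), hit(20, 30, e=10.0), hit(40, 50, e=11.0)]
    kept = filter_hits(hits)
    assert [h.e_value for h in kept] == [0.001, 10.0]
    # content untouched, only membership changes
    assert kept[0] is hits[0] and kept[1] is hits[1]
    assert filter_hits([]) == []


# ---------------------------------------------------------------------------
# merging

def test_merge_overlapping_hits():
    calls = merge_hits_to_domains([hit(100, 200), hit(150, 300)])
    assert len(calls) == 1
    assert (calls[0].interval.start, calls[0].interval.end) == (100, 300)
    assert len(calls[0].supporting_hits) == 2


def test_merge_keeps_strands_separate():
    calls = merge_hits_to_domains([hit(100, 200), hit(100, 200, strand=Strand.MINUS)])
    assert len(calls) == 2


def test_merge_abutting_vs_one_bp_gap():
    # end == start abuts and merges; a 1-bp gap stays split
    assert len(merge_hits_to_domains([hit(0, 10), hit(10, 20)])) == 1
    assert len(merge_hits_to_domains([hit(0, 10), hit(11, 20)])) == 2


def test_merge_maps_pfam_accessions():
    calls = merge_hits_to_domains([hit(0, 10, label="PF00047"), hit(50, 60, label="PF00059")])
    assert {c.domain_label for c in calls} == {"IGSF", "CLEC"}
    assert merge_hits_to_domains([hit(0, 10, label="RSS")])[0].domain_label == "RSS"


def test_merge_best_e_value_is_min():
    calls = merge_hits_to_domains([hit(0, 10, e=1e-3), hit(5, 15, e=1e-9)])
    assert calls[0].best_e_value == 1e-9


# ---------------------------------------------------------------------------
# chaining

def test_chain_gap_rule_worked_examples():
    # two IGSF domains 3 kbp apart belong to one gene; 6 kbp apart to two
    one = chain_domains_to_genes([domain(0, 1000), domain(4000, 5000)])
    assert len(one) == 1 and len(one[0].exons) == 2
    assert (one[0].span.start, one[0].span.end) == (0, 5000)
    two = chain_domains_to_genes([domain(0, 1000), domain(7000, 8000)])
    assert len(two) == 2


def test_chain_single_domain_and_strand_awareness():
    assert len(chain_domains_to_genes([domain(0, 1000)])) == 1
    mixed = [domain(0, 1000), domain(2000, 3000, strand=Strand.MINUS)]
    assert len(chain_domains_to_genes(mixed)) == 2
    assert len(chain_domains_to_genes(mixed, strand_aware=False)) == 1


def test_chain_boundary_gap_exactly_max():
    exactly = chain_domains_to_genes([domain(0, 1000), domain(6000, 7000)], max_gap=5000)
    assert len(exactly) == 1
    over = chain_domains_to_genes([domain(0, 1000), domain(6001, 7000)], max_gap=5000)
    assert len(over) == 2


def oracle_clusters(intervals, max_gap):
    """Transitive closure of the pairwise 'within max_gap' relation."""
    n = len(intervals)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = intervals[i], intervals[j]
            gap = max(a[0], b[0]) - min(a[1], b[1])
            if gap <= max_gap:
                parent[find(i)] = find(j)
    return sorted(
        sorted(tuple(sorted(i for i in range(n) if find(i) == r)) for r in set(map(find, range(n))))
    )


@settings(max_examples=150, deadline=None)
@given(
    ivs=st.lists(st.tuples(st.integers(0, 50_000), st.integers(1, 3_000)),
                 min_size=1, max_size=50),
    max_gap=st.sampled_from([0, 500, 5000]),
)
def test_merge_then_chain_equals_transitive_closure(ivs, max_gap):
    hits = [hit(a, a + l, q=f"h{i}") for i, (a, l) in enumerate(ivs)]
    domains = merge_hits_to_domains(hits)
    cands = chain_domains_to_genes(domains, max_gap=max_gap)
    got = sorted(
        sorted(tuple(sorted(int(h[1:]) for d in c.exons for h in d.supporting_hits)) for c in cands)
    )
    expected = oracle_clusters([(a, a + l) for a, l in ivs], max_gap)
    assert got == expected
    # maximality: internal gaps within max_gap, candidates separated by more
    for c in cands:
        ends = 0
        for i, d in enumerate(c.exons):
            if i:
                assert d.interval.start - ends <= max_gap
            ends = max(ends, d.interval.end)
    spans = sorted((c.span.start, c.span.end) for c in cands)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        assert s2 - e1 > max_gap


def test_chain_is_order_independent_and_idempotent():
    ds = [domain(0, 1000), domain(4000, 5000), domain(20_000, 21_000)]
    a = chain_domains_to_genes(ds)
    b = chain_domains_to_genes(list(reversed(ds)))
    assert [c.span for c in a] == [c.span for c in b]
    rechained = chain_domains_to_genes([d for c in a for d in c.exons])
    assert [c.span for c in rechained] == [c.span for c in a]


# ---------------------------------------------------------------------------
# RSS pairing

def v_candidate(start, end, strand=Strand.PLUS, scaffold="s1"):
    d = domain(start, end, scaffold=scaffold, strand=strand, label="V-segment")
    (cand,) = chain_domains_to_genes([d], family=Family.IG_V)
    return cand


def test_rss_downstream_within_window_flanks():
    cand = v_candidate(1000, 1300)
    rss = [domain(1310, 1349, label="RSS")]
    (out,) = pair_rss_to_v_segments([cand], rss, window=60)
    assert out.rss_flanked is True


def test_rss_strand_mismatch_does_not_flank():
    cand = v_candidate(1000, 1300)
    rss = [domain(1310, 1349, strand=Strand.MINUS, label="RSS")]
    (out,) = pair_rss_to_v_segments([cand], rss, window=60)
    assert out.rss_flanked is False


def test_rss_minus_strand_three_prime_is_upstream():
    cand = v_candidate(1000, 1300, strand=Strand.MINUS)
    # 3' end of a minus-strand segment is its lower coordinate
    (out,) = pair_rss_to_v_segments([cand], [domain(950, 990, strand=Strand.MINUS, label="RSS")])
    assert out.rss_flanked is True
    (out2,) = pair_rss_to_v_segments([cand], [domain(1310, 1349, strand=Strand.MINUS, label="RSS")])
    assert out2.rss_flanked is False


def test_rss_absent_or_too_far():
    cand = v_candidate(1000, 1300)
    (out,) = pair_rss_to_v_segments([cand], [])
    assert out.rss_flanked is False
    (far,) = pair_rss_to_v_segments([cand], [domain(1400, 1440, label="RSS")], window=60)
    assert far.rss_flanked is False


# ---------------------------------------------------------------------------
# retention gate

def test_retention_gate():
    cand = v_candidate(0, 300)
    kept = apply_retention_gate(cand, {"c1": {"PF00047"}}, candidate_id="c1")
    assert kept.retained is True and kept.rejection_reason is None
    rejected = apply_retention_gate(cand, {"c1": {"keratin"}}, candidate_id="c1")
    assert rejected.retained is False
    assert rejected.rejection_reason == "no qualifying top hit"
    empty = apply_retention_gate(cand, {"c1": set()}, candidate_id="c1")
    assert empty.retained is False
    absent = apply_retention_gate(cand, {}, candidate_id="c1")
    assert absent.rejection_reason == "no top hit evidence"


# ---------------------------------------------------------------------------
# naming

def test_positional_naming():
    cands = [v_candidate(s, s + 300) for s in (90_000, 500, 10_000)]
    named = assign_gene_names(cands, Family.IG_V, "IGHV")
    assert [c.name for c in named] == ["IGHV1", "IGHV2", "IGHV3"]
    assert [c.span.start for c in named] == [500, 10_000, 90_000]


def test_naming_single_and_tie_warning():
    (one,) = assign_gene_names([v_candidate(500, 800)], Family.IG_V, "X")
    assert one.name == "X1"
    dup = [v_candidate(500, 800), v_candidate(500, 800)]
    with pytest.warns(UserWarning, match="identical"):
        named = assign_gene_names(dup, Family.IG_V, "X")
    assert [c.name for c in named] == ["X1", "X2"]


def test_naming_is_bijection_onto_ranks():
    cands = [v_candidate(1000 * i, 1000 * i + 300) for i in range(7)]
    named = assign_gene_names(cands, Family.IG_V, "V")
    assert sorted(c.name for c in named) == sorted(f"V{i + 1}" for i in range(7))
    assert len({c.name for c in named}) == 7
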