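"""Simulator properties: determinism, conservation of gene content through
fragmentation and scaffolding, exact recovery under error-free
scaffolding, and calibration of the annotation-degradation model."""

import numpy as np
import pytest

from immucontig.contiguity import gene_set_L
from immucontig.concordance import summarize_concordance
from immucontig.io import write_annotation
from immucontig.model import Strand
from immucontig.simulate import (
    FamilyConfig,
    SimulationConfig,
    default_config,
    degrade_annotation,
    fragment_assembly,
    scaffold_with_errors,
    simulate_truth,
)


def small_config(seed=1, **kw):
    fams = (FamilyConfig("LRC", 10, cluster_scaffold="chr1"),)
    defaults = dict(chromosome_count=1, chromosome_length=300_000)
    defaults.update(kw)
    return SimulationConfig(families=fams, seed=seed, **defaults)


def test_single_cluster_truth_layout():
    t = simulate_truth(small_config())
    assert len(t.annotation) == 10
    assert gene_set_L(t.annotation, 0.9) == 1
    spans = sorted((g.span.start, g.span.end) for g in t.annotation)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        assert s2 > e1  # non-overlapping cluster members


def test_truth_determinism_byte_identical(tmp_path):
    a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
    write_annotation(simulate_truth(small_config()).annotation, a, "tsv")
    write_annotation(simulate_truth(small_config()).annotation, b, "tsv")
    assert a.read_bytes() == b.read_bytes()


def test_zero_cv_gives_exact_gene_lengths():
    cfg = SimulationConfig(
        families=(FamilyConfig("LRC", 8, gene_length_cv=0.0),),
        seed=3,
        chromosome_count=1,
        chromosome_length=300_000,
    )
    t = simulate_truth(cfg)
    assert all(g.length == 10_000 for g in t.annotation)


def test_cluster_too_large_raises_with_required_length():
    cfg = SimulationConfig(
        families=(FamilyConfig("LRC", 50),), seed=1,
        chromosome_count=1, chromosome_length=100_000,
    )
    with pytest.raises(ValueError, match="chromosome length"):
        simulate_truth(cfg)


def test_fragmentation_hits_target_window_and_conserves_genes():
    t = simulate_truth(default_config(seed=5))
    target = 200_000
    f = fragment_assembly(t, target, seed=5)
    n50 = f.assembly.scaffold_N50
    assert 0.5 * target <= n50 <= 2 * target
    # conservation: fragments of each parent sum to the truth length
    truth_len = {g.gene_id: g.length for g in t.annotation}
    seen = {}
    primaries = set()
    for g in f.annotation:
        parent = g.parent_id or g.gene_id
        seen[parent] = seen.get(parent, 0) + g.length
        if g.is_primary:
            primaries.add(parent)
    assert seen == truth_len
    assert primaries == set(truth_len)  # exactly one primary per parent


def test_fragmentation_no_breakpoints_at_chromosome_scale_target():
    cfg = small_config()
    t = simulate_truth(cfg)
    f = fragment_assembly(t, cfg.chromosome_length, seed=1)
    assert len(f.breakpoints) == 0
    assert len(f.assembly) == 1
    assert sorted(g.gene_id for g in f.annotation) == sorted(
        g.gene_id for g in t.annotation
    )


def test_fragmentation_infeasible_target_rejected():
    t = simulate_truth(small_config())
    with pytest.raises(ValueError, match="infeasible"):
        fragment_assembly(t, 10_000_000, seed=1)


def test_error_free_scaffolding_recovers_truth_exactly():
    t = simulate_truth(default_config(seed=7))
    f = fragment_assembly(t, 100_000, seed=7)
    s = scaffold_with_errors(f, inversion_rate=0.0, misjoin_rate=0.0, seed=7)
    # same L statistics...
    assert gene_set_L(s.annotation, 0.5) == gene_set_L(t.annotation, 0.5)
    assert gene_set_L(s.annotation, 0.9) == gene_set_L(t.annotation, 0.9)
    # ...and in fact identical gene coordinates, fragments re-fused
    got = {
        g.gene_id: (g.scaffold.removeprefix("scaf_"), g.span.start, g.span.end,
                    g.span.strand, len(g.exons))
        for g in s.annotation
    }
    want = {
        g.gene_id: (g.scaffold, g.span.start, g.span.end, g.span.strand, len(g.exons))
        for g in t.annotation
    }
    assert got == want


def test_full_inversion_flips_second_contig_genes():
    cfg = small_config()
    t = simulate_truth(cfg)
    # force exactly one breakpoint in the middle of the cluster
    f = fragment_assembly(t, cfg.chromosome_length // 2, seed=2)
    assert len(f.assembly) >= 2
    s = scaffold_with_errors(f, inversion_rate=1.0, misjoin_rate=0.0, seed=2)
    layout = s.layout
    assert not layout.iloc[0]["inverted"]  # first contig anchors
    assert layout.iloc[1:]["inverted"].all()


def test_inversion_flips_strand_of_affected_genes():
    cfg = small_config()
    t = simulate_truth(cfg)
    f = fragment_assembly(t, cfg.chromosome_length // 2, seed=4)
    s = scaffold_with_errors(f, inversion_rate=1.0, misjoin_rate=0.0, seed=4)
    inverted = set(s.layout[s.layout["inverted"]]["contig"])
    strands = {g.gene_id: g.span.strand for g in s.annotation}
    for g in f.annotation:
        if g.scaffold in inverted and g.gene_id in strands:
            assert strands[g.gene_id] == g.span.strand.flipped()
        elif g.scaffold not in inverted and g.gene_id in strands:
            assert strands[g.gene_id] == g.span.strand


def test_certain_misjoins_mix_chromosomes():
    t = simulate_truth(default_config(seed=9))
    f = fragment_assembly(t, 500_000, seed=9)
    assert all(len(v) >= 2 for v in f.contig_order.values())
    s = scaffold_with_errors(f, inversion_rate=0.0, misjoin_rate=1.0, seed=9)
    sources = s.layout.assign(chrom=s.layout["contig"].str.rsplit("_c", n=1).str[0])
    per_scaffold = sources.groupby("scaffold")["chrom"].nunique()
    assert (per_scaffold >= 2).all()
    # contig multiset conserved
    assert sorted(s.layout["contig"]) == sorted(f.assembly.scaffold_lengths)


def test_degrade_miss_rate_one_empty():
    t = simulate_truth(small_config())
    auto = degrade_annotation(t.annotation, 1.0, (9, 1), seed=1)
    assert len(auto) == 0
    assert summarize_concordance(t.annotation, auto).total.pct_missing == 100.0


def test_degrade_perfect_annotation():
    t = simulate_truth(small_config())
    auto = degrade_annotation(t.annotation, 0.0, None, seed=1)
    s = summarize_concordance(t.annotation, auto)
    assert s.total.pct_correct == 100.0
    assert s.total.pct_missing == 0.0


def test_degrade_mean_overlap_matches_beta_expectation():
    cfg = SimulationConfig(
        families=(FamilyConfig("cytokine", 500, intergenic_mean=1_000),),
        seed=11, chromosome_count=1, chromosome_length=9_000_000,
    )
    t = simulate_truth(cfg)
    auto = degrade_annotation(t.annotation, 0.0, (9, 1), seed=11)
    s = summarize_concordance(t.annotation, auto)
    mean_overlap = float(np.mean([r.gene_overlap for r in s.records]))
    assert mean_overlap == pytest.approx(0.9, abs=0.03)


def test_degrade_split_models_cover_same_bases():
    t = simulate_truth(small_config())
    whole = degrade_annotation(t.annotation, 0.0, (5, 2), seed=3, split_prob=0.0)
    split = degrade_annotation(t.annotation, 0.0, (5, 2), seed=3, split_prob=1.0)
    s1 = summarize_concordance(t.annotation, whole)
    s2 = summarize_concordance(t.annotation, split)
    assert [r.gene_overlap for r in s1.records] == pytest.approx(
        [r.gene_overlap for r in s2.records]
    )
    assert len(split) >= len(whole)
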