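import itertools
import math

import numpy as np
import pandas as pd
import pytest

from mitotempo import popgen_stats as ps
from mitotempo import serial_coalescent as sc
from mitotempo import synthetic_data as sd
from mitotempo.alignment_io import Alignment, alignment_from_codes
from mitotempo.popgen_stats import UndefinedStatistic


# ---------------------------------------------------------------------------
# haplotype calling
# ---------------------------------------------------------------------------

def test_identical_sequences_one_haplotype():
    aln = Alignment(("a", "b", "c", "d"), ("ACGT",) * 4)
    table = ps.call_haplotypes(aln)
    assert table.H == 1 and table.counts == (4,)


def test_two_haplotypes_with_counts():
    aln = Alignment(("a", "b", "c"), ("AA", "AT", "AA"))
    table = ps.call_haplotypes(aln)
    assert table.H == 2 and sorted(table.counts) == [1, 2]


def test_compatible_merge_with_missing(fixtures):
    aln, truth = fixtures["missing_trio"]
    assert ps.call_haplotypes(aln, mode="compatible").H == truth["H_compatible"]
    # the ambiguous sequence joins the most-complete compatible cluster
    table = ps.call_haplotypes(aln, mode="compatible")
    by_label = {h.label: h.member_ids for h in table.haplotypes}
    assert by_label["a"] == ("a", "b")


def test_strict_mode_excludes_missing_columns():
    # column 1 has an N, so strict mode compares column 0 only: A,A,T
    aln = Alignment(("a", "b", "c"), ("AA", "AN", "TT"))
    assert ps.call_haplotypes(aln, mode="strict").H == 2
    # with a conflicting resolved site, strict and compatible differ
    aln2 = Alignment(("a", "b", "c"), ("AAC", "ANC", "AGC"))
    assert ps.call_haplotypes(aln2, mode="compatible").H == 2
    assert ps.call_haplotypes(aln2, mode="strict").H == 1  # middle column dropped


def test_haplotype_labels_deterministic(mountain_study):
    aln, _, _ = mountain_study
    t1 = ps.call_haplotypes(aln)
    t2 = ps.call_haplotypes(aln)
    assert [h.label for h in t1.haplotypes] == [h.label for h in t2.haplotypes]
    for h in t1.haplotypes:
        assert h.label == min(h.member_ids)


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

def test_haplotype_diversity_extremes():
    assert ps.haplotype_diversity([4]) == 0.0
    assert ps.haplotype_diversity([1, 1, 1, 1]) == pytest.approx(1.0)
    assert ps.haplotype_diversity([2, 1, 1]) == pytest.approx(0.8333, abs=1e-4)
    with pytest.raises(UndefinedStatistic):
        ps.haplotype_diversity([1])


def test_pairwise_diff_stats_hand_enumeration():
    aln = Alignment(("a", "b", "c"), ("AAAAAAAAAA", "AAAAAAAAAT", "AAAAAAAATT"))
    k_bar, pi = ps.pairwise_diff_stats(aln)
    assert k_bar == pytest.approx(4 / 3)
    assert pi == pytest.approx(0.13333, abs=1e-5)


def test_pairwise_identical_and_permutation_invariance(mountain_study):
    assert ps.pairwise_diff_stats(Alignment(("a", "b"), ("AC", "AC"))) == (0.0, 0.0)
    aln, _, _ = mountain_study
    rng = np.random.default_rng(0)
    perm = list(rng.permutation(aln.ids))
    assert ps.pairwise_diff_stats(aln) == ps.pairwise_diff_stats(aln.subset(perm))


def test_pairwise_deletion_uses_resolved_length():
    # pair differs at 1 of 2 comparable sites -> pi = 0.5, not 0.25
    aln = Alignment(("a", "b"), ("ATNN", "AANN"))
    k_bar, pi = ps.pairwise_diff_stats(aln)
    assert (k_bar, pi) == (1.0, 0.5)


def test_hd_zero_iff_single_haplotype(mountain_study):
    aln, _, _ = mountain_study
    table = ps.call_haplotypes(aln)
    hd = ps.haplotype_diversity(table.counts)
    assert (hd == 0.0) == (table.H == 1)
    assert 0.0 <= hd <= 1.0


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def test_tajimas_d_hand_fixture(fixtures):
    aln, truth = fixtures["tajima_n4"]
    assert ps.tajimas_d(aln) == pytest.approx(truth["tajima_d"], abs=1e-3)


def test_tajimas_d_undefined_cases(fixtures):
    mono, _ = fixtures["mono"]
    with pytest.raises(UndefinedStatistic):
        ps.tajimas_d(mono)
    with pytest.raises(UndefinedStatistic):
        ps.tajimas_d(Alignment(("a", "b", "c"), ("AT", "TA", "AA")))


def test_tajimas_d_centered_under_neutral_constant_size():
    """Mean D over neutral constant-size replicates stays near 0."""
    design = sc.SamplingDesign(((0.0, 12),))
    demo = sc.constant_model(1500.0)
    mut = sc.MutationModel(rate=1.28e-8, ts_tv_bias=1.0, length=8000)
    rng = np.random.default_rng(2024)
    values = []
    for _ in range(600):
        aln, _ = sc.simulate_dataset(design, demo, mut, rng)
        try:
            values.append(ps.tajimas_d(aln))
        except UndefinedStatistic:
            continue
    assert abs(np.mean(values)) < 0.15


# ---------------------------------------------------------------------------
# F_ST and private haplotypes
# ---------------------------------------------------------------------------

def test_fst_fixed_difference(fixtures):
    aln, truth = fixtures["fst_fixed"]
    a = aln.subset(truth["groups"]["A"])
    b = aln.subset(truth["groups"]["B"])
    assert ps.hudson_fst(a, b) == pytest.approx(truth["fst"])
    assert ps.mean_between_diffs(a, b) == pytest.approx(truth["k_between"])


def test_fst_identical_groups_zero(mountain_study):
    aln, _, _ = mountain_study
    assert ps.hudson_fst(aln, aln) == pytest.approx(0.0)


def test_fst_undefined_when_monomorphic():
    a = Alignment(("a1", "a2"), ("AAAA", "AAAA"))
    with pytest.raises(UndefinedStatistic):
        ps.hudson_fst(a, a)


def test_fst_panmictic_mean_near_zero():
    """Two arbitrary halves of one panmictic sample: mean F_ST within 3 SE of 0."""
    design = sc.SamplingDesign(((0.0, 12),))
    demo = sc.constant_model(1500.0)
    mut = sc.MutationModel(rate=1.28e-8, ts_tv_bias=1.0, length=8000)
    rng = np.random.default_rng(99)
    values = []
    for _ in range(300):
        aln, _ = sc.simulate_dataset(design, demo, mut, rng)
        a = aln.subset(list(aln.ids[:6]))
        b = aln.subset(list(aln.ids[6:]))
        try:
            values.append(ps.hudson_fst(a, b))
        except UndefinedStatistic:
            continue
    se = np.std(values, ddof=1) / math.sqrt(len(values))
    assert abs(np.mean(values)) < 3 * se


def test_private_haplotypes_disjoint_and_identical():
    a = Alignment(("a1", "a2", "a3"), ("AA", "AT", "AA"))
    b = Alignment(("b1", "b2"), ("TT", "TT"))
    assert ps.private_haplotypes(ps.call_haplotypes(a), ps.call_haplotypes(b)) == (2, 1, 0)
    ta = ps.call_haplotypes(a)
    assert ps.private_haplotypes(ta, ta) == (0, 0, 2)


def test_private_haplotypes_mountain_pattern():
    """4 historical haplotypes, 2 modern of which 1 shared -> (3, 1, 1)."""
    hist = Alignment(
        ("h1", "h2", "h3", "h4"), ("AAAA", "AAAT", "AATT", "ATTT")
    )
    modern = Alignment(("m1", "m2"), ("AAAA", "TTTT"))
    priv_h, priv_m, shared = ps.private_haplotypes(
        ps.call_haplotypes(hist), ps.call_haplotypes(modern)
    )
    assert (priv_h, priv_m, shared) == (3, 1, 1)


# ---------------------------------------------------------------------------
# variant classification
# ---------------------------------------------------------------------------

def _single_gene_annotation(length, strand="+", kind="coding"):
    return pd.DataFrame([
        {"gene": "G1", "start": 0, "end": length, "strand": strand,
         "frame": 0, "type": kind}
    ])


def test_transition_vs_transversion():
    aln = Alignment(("a", "b"), ("AAA", "GAA"))
    ann = pd.DataFrame(columns=["gene", "start", "end", "strand", "frame", "type"])
    (v,) = ps.classify_variants(aln, ann)
    assert v.substitution_class == "transition" and v.context == "non-coding"
    aln2 = Alignment(("a", "b"), ("AAA", "CAA"))
    (v2,) = ps.classify_variants(aln2, ann)
    assert v2.substitution_class == "transversion"


def test_synonymous_codon():
    # GGA -> GGG is Gly -> Gly
    aln = Alignment(("a", "b", "c"), ("GGA", "GGG", "GGA"))
    (v,) = ps.classify_variants(aln, _single_gene_annotation(3))
    assert v.coding_effect == "synonymous" and v.gene == "G1"


def test_nonsynonymous_pam250_score():
    # ATA (Met in the vertebrate mito code) -> GTA (Val): PAM250(M,V) = 2 >= 0
    aln = Alignment(("a", "b", "c"), ("ATA", "GTA", "ATA"))
    (v,) = ps.classify_variants(aln, _single_gene_annotation(3))
    assert v.coding_effect == "nonsynonymous"
    assert v.pam250 == 2 and v.commonly_observed is True


def test_stop_gained_flagged():
    # TGG (Trp) -> TAG (stop) in the vertebrate mito code
    aln = Alignment(("a", "b", "c"), ("TGG", "TAG", "TGG"))
    (v,) = ps.classify_variants(aln, _single_gene_annotation(3))
    assert v.coding_effect == "stop_gained" and v.stop_gained


def test_minus_strand_codon():
    # gene on '-': genomic TAT|... read as reverse complement ATA (Met);
    # variant A->C at genomic pos 0 makes TCT -> revcomp AGA = stop (mito)
    aln = Alignment(("a", "b", "c"), ("TAT", "TCT", "TAT"))
    (v,) = ps.classify_variants(aln, _single_gene_annotation(3, strand="-"))
    assert v.position == 1
    assert v.coding_effect == "stop_gained"


def test_multiallelic_reported_and_tally_totals(mountain_study):
    aln = Alignment(("a", "b", "c"), ("A", "C", "G"))
    ann = pd.DataFrame(columns=["gene", "start", "end", "strand", "frame", "type"])
    (v,) = ps.classify_variants(aln, ann)
    assert v.substitution_class == "multiallelic"
    # Ts + Tv + multiallelic = S on simulated data
    study, _, _ = mountain_study
    ann2 = sd.default_annotation(study.length)
    variants = ps.classify_variants(study, ann2)
    ts, tv, multi = ps.ts_tv_tally(variants)
    assert ts + tv + multi == ps.segregating_sites(study)
    assert len(variants) == ps.segregating_sites(study)


# ---------------------------------------------------------------------------
# minimum spanning network
# ---------------------------------------------------------------------------

def _mst_weight_brute_force(table):
    """Exhaustive minimum over all spanning trees (H <= 7)."""
    import networkx as nx

    haps = table.haplotypes
    labels = [h.label for h in haps]
    codes = {h.label: Alignment((h.label,), (h.representative,)).to_codes()[0]
             for h in haps}
    edges = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            w = int(((codes[a] != codes[b]) & (codes[a] < 4) & (codes[b] < 4)).sum())
            edges.append((a, b, w))
    best = math.inf
    for combo in itertools.combinations(edges, len(labels) - 1):
        g = nx.Graph()
        g.add_nodes_from(labels)
        g.add_weighted_edges_from(combo)
        if g.number_of_edges() == len(labels) - 1 and nx.is_connected(g):
            best = min(best, sum(w for _, _, w in combo))
    return best


def test_msn_single_haplotype():
    aln = Alignment(("a", "b"), ("ACGT", "ACGT"))
    net = ps.min_spanning_network(ps.call_haplotypes(aln))
    assert net.graph.number_of_nodes() == 1 and net.graph.number_of_edges() == 0


def test_msn_three_haplotypes_tied():
    # d(h1,h2)=1, d(h1,h3)=2, d(h2,h3)=1 -> MST edges {12, 23}, weight 2
    aln = Alignment(("h1", "h2", "h3"), ("AAA", "AAT", "ATT"))
    net = ps.min_spanning_network(ps.call_haplotypes(aln))
    assert net.edge_list() == [("h1", "h2", 1), ("h2", "h3", 1)]
    assert net.total_mst_weight == 2


def test_msn_matches_brute_force_minimum(mountain_study):
    aln, _, _ = mountain_study
    table = ps.call_haplotypes(aln)
    if table.H > 7:  # keep enumeration tractable: collapse to 7 haplotypes
        ids = [h.member_ids[0] for h in table.haplotypes[:7]]
        table = ps.call_haplotypes(aln.subset(ids))
    net = ps.min_spanning_network(table)
    assert net.graph.number_of_nodes() == table.H
    import networkx as nx
    assert nx.is_connected(net.graph)
    assert net.graph.number_of_edges() >= table.H - 1
    assert all(d["weight"] >= 1 for _, _, d in net.graph.edges(data=True))
    if table.H >= 2:
        assert net.total_mst_weight == _mst_weight_brute_force(table)


def test_diversity_table_per_group(grauer_study):
    from mitotempo import alignment_io as aio
    aln, meta, _ = grauer_study
    groups = aio.partition(aln, meta, ("era",))
    df = ps.diversity_table(groups)
    assert set(df["group"]) == {"historical", "modern"}
    assert (df["n"] >= 2).all() and np.isfinite(df["Hd"]).all()
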