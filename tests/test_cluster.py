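"""Similarity graph, Markov clustering, protein similarity and NJ trees."""

import itertools

import numpy as np
import pytest

from tbescan.cluster import (
    ClusterConfig,
    SimilarityGraph,
    all_vs_all_similarity,
    mcl,
    neighbor_joining,
    pairwise_protein_similarity,
    protein_percent_similarity,
    two_pass_cluster,
)


def clique_graph(groups, within=90.0, bridges=()):
    nodes = [n for g in groups for n in g]
    g = SimilarityGraph(nodes=nodes)
    for grp in groups:
        for a, b in itertools.combinations(grp, 2):
            g.add_edge(a, b, within)
    for a, b, w in bridges:
        g.add_edge(a, b, w)
    return g


class TestMCL:
    def test_disconnected_triangles_two_clusters(self):
        g = clique_graph([list("abc"), list("def")])
        cs = mcl(g)
        assert sorted(sorted(c) for c in cs.clusters) == [list("abc"), list("def")]

    def test_single_node(self):
        assert mcl(SimilarityGraph(nodes=["x"])).clusters == [["x"]]

    def test_partition_property(self):
        g = clique_graph([list("abcd"), list("efgh")], bridges=[("a", "e", 70.0)])
        cs = mcl(g)
        flat = sorted(n for c in cs.clusters for n in c)
        assert flat == sorted(g.nodes)

    def test_bridged_cliques_separate_at_higher_inflation(self):
        g = clique_graph([list("abcd"), list("efgh")], bridges=[("a", "e", 70.0)])
        cs = mcl(g, ClusterConfig(inflation=2.0))
        assert sorted(len(c) for c in cs.clusters) == [4, 4]
        # inflation 1.2 is deliberately coarse: the same graph merges
        cs_coarse = mcl(g, ClusterConfig(inflation=1.2))
        assert len(cs_coarse.clusters) == 1

    def test_invariance_to_node_order_and_weight_scale(self):
        base = clique_graph([list("abcd"), list("efgh")])
        cs1 = mcl(base)
        shuffled = SimilarityGraph(nodes=list("hgfedcba"), edges=dict(base.edges))
        cs2 = mcl(shuffled)
        scaled = SimilarityGraph(
            nodes=base.nodes, edges={k: w * 0.5 for k, w in base.edges.items()}
        )
        cs3 = mcl(scaled)
        as_sets = lambda cs: sorted(sorted(c) for c in cs.clusters)
        assert as_sets(cs1) == as_sets(cs2) == as_sets(cs3)

    def test_inflation_must_exceed_one(self):
        with pytest.raises(ValueError):
            ClusterConfig(inflation=1.0)


class TestAllVsAll:
    def test_identical_sequences_weight_100(self, rng):
        s = "".join(rng.choice(list("ACGT"), 300))
        g = all_vs_all_similarity({"a": s, "b": s})
        assert g.edges == {("a", "b"): 100.0}

    def test_no_common_word_no_edge(self, rng):
        a = "".join(rng.choice(list("ACGT"), 300))
        b = "".join(rng.choice(list("ACGT"), 300))
        g = all_vs_all_similarity({"a": a, "b": b}, word_size=50)
        assert g.edges == {}

    def test_five_percent_divergence_weight(self, rng):
        a = "".join(rng.choice(list("ACGT"), 1000))
        b = list(a)
        for i in range(len(b)):
            if rng.random() < 0.05:
                b[i] = rng.choice([c for c in "ACGT" if c != b[i]])
        cfg = ClusterConfig(anchor_word_size=20, min_edge_weight=0.0)
        g = all_vs_all_similarity({"a": a, "b": "".join(b)}, cfg)
        assert g.edges[("a", "b")] == pytest.approx(95.0, abs=2.0)


def test_two_pass_splits_cds_defined_subfamilies(rng):
    """Elements identical except for a divergent second half: one first-pass
    cluster, split by the CDS pass."""
    shared = "".join(rng.choice(list("ACGT"), 1500))
    cds_a = "".join(rng.choice(list("ACGT"), 900))
    cds_b = "".join(rng.choice(list("ACGT"), 900))

    def noisy(s):
        out = list(s)
        for i in range(len(out)):
            if rng.random() < 0.03:
                out[i] = rng.choice([c for c in "ACGT" if c != out[i]])
        return "".join(out)

    elems, cds = {}, {}
    for i in range(5):
        cds_i = noisy(cds_a)
        elems[f"a{i}"] = noisy(shared) + cds_i
        cds[f"a{i}"] = cds_i
    for i in range(5):
        cds_i = noisy(cds_b)
        elems[f"b{i}"] = noisy(shared) + cds_i
        cds[f"b{i}"] = cds_i
    cfg = ClusterConfig(anchor_word_size=28, cds_anchor_word_size=24)
    cs = two_pass_cluster(elems, cds, cfg)
    assert len(cs.clusters) == 2
    sides = [{n[0] for n in c} for c in cs.clusters]
    assert sides == [{"a"}, {"b"}] or sides == [{"b"}, {"a"}]


class TestProteinSimilarity:
    def test_identical_proteins(self):
        p = "MKVLYRAEDWQNH" * 10
        df = pairwise_protein_similarity({"g": [p, p, p]})
        row = df.iloc[0]
        assert row["mean"] == 100.0 and row["sd"] == 0.0
        assert row["n_pairs"] == 3  # n*(n-1)/2 distinct unordered pairs

    def test_within_group_counts_distinct_pairs(self):
        p = "MKVLYRAEDWQNH" * 5
        df = pairwise_protein_similarity({"g": [p] * 5, "h": [p] * 3})
        n = {(r.group_a, r.group_b): r.n_pairs for r in df.itertuples()}
        assert n[("g", "g")] == 10 and n[("h", "h")] == 3 and n[("g", "h")] == 15

    def test_similarity_decreases_with_divergence(self, rng):
        aas = list("ARNDCQEGHILKMFPSTWYV")
        base = "".join(rng.choice(aas, 200))

        def mutate(p, rate):
            return "".join(
                rng.choice(aas) if rng.random() < rate else c for c in p
            )

        near = protein_percent_similarity(base, mutate(base, 0.1))
        far = protein_percent_similarity(base, mutate(base, 0.5))
        assert 100.0 > near > far


class TestNeighborJoining:
    def test_additive_matrix_recovered_exactly(self):
        # tree ((A:2,B:3):1,(C:4,D:5)); path lengths below
        labels = ["A", "B", "C", "D"]
        d = np.array(
            [[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]], dtype=float
        )
        tree = neighbor_joining(labels, d)
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    assert tree.find(a).distance(tree.find(b)) == pytest.approx(d[i, j])

    def test_three_taxa_closed_form(self):
        labels = ["A", "B", "C"]
        d = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], dtype=float)
        tree = neighbor_joining(labels, d)
        # star resolution: branch lengths (d_ab + d_ac - d_bc)/2 etc.
        assert tree.find("A").distance(tree.find("B")) == pytest.approx(2.0)
        assert tree.find("A").distance(tree.find("C")) == pytest.approx(3.0)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(["A", "B"], np.array([[0, 1], [1, 0]], dtype=float))

    def test_newick_round_trip(self, tmp_path):
        import skbio

        labels = ["A", "B", "C", "D"]
        d = np.array(
            [[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]], dtype=float
        )
        tree = neighbor_joining(labels, d)
        path = tmp_path / "t.nwk"
        tree.write(str(path), format="newick")
        back = skbio.TreeNode.read(str(path), format="newick")
        for a, b in itertools.combinations(labels, 2):
            assert back.find(a).distance(back.find(b)) == pytest.approx(
                tree.find(a).distance(tree.find(b)), rel=1e-6
            )
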