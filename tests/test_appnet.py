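import random

import pytest

from mixmod import (
    BenchmarkSpec,
    HetNetError,
    Partition,
    as_fingerprint,
    build_2hn,
    gene_edges,
    generate_benchmark,
    label_permutation_test,
    similarity_edges,
    similarity_interaction_correlation,
    tanimoto,
    target_sets,
)


FP = {
    "c1": as_fingerprint("111100"),
    "c2": as_fingerprint("111000"),
    "c3": as_fingerprint("000011"),
}


class TestTanimoto:
    def test_identity(self):
        assert tanimoto(FP["c1"], FP["c1"]) == 1.0

    def test_disjoint(self):
        assert tanimoto(FP["c1"], FP["c3"]) == 0.0

    def test_half_overlap(self):
        # |AND| = 3, |OR| = 6
        f1 = as_fingerprint("111100")
        f2 = as_fingerprint("111011")
        assert tanimoto(f1, f2) == pytest.approx(3 / 6)

    def test_symmetry(self):
        assert tanimoto(FP["c1"], FP["c2"]) == tanimoto(FP["c2"], FP["c1"])

    def test_all_zero_pair_rejected(self):
        with pytest.raises(HetNetError):
            tanimoto(frozenset(), frozenset())


class TestSimilarityEdges:
    def test_threshold_is_inclusive(self):
        fps = {"x": as_fingerprint("1111111000"), "y": as_fingerprint("1111111111")}
        assert tanimoto(fps["x"], fps["y"]) == pytest.approx(0.7)
        assert len(similarity_edges(fps, threshold=0.7)) == 1

    def test_below_threshold_excluded(self):
        # similarity 9/13 = 0.692 < 0.7
        fps = {"x": as_fingerprint("1" * 9 + "0000"), "y": as_fingerprint("1" * 13)}
        assert tanimoto(fps["x"], fps["y"]) < 0.7
        assert similarity_edges(fps, threshold=0.7) == []

    def test_identical_triple_gives_triangle(self):
        fps = {k: as_fingerprint("1010") for k in ("x", "y", "z")}
        assert len(similarity_edges(fps)) == 3

    def test_weighted_mode_stores_similarity(self):
        fps = {"x": as_fingerprint("1111111000"), "y": as_fingerprint("1111111111")}
        (u, v, w), = similarity_edges(fps, weighted=True)
        assert w == pytest.approx(0.7)


class TestGeneEdges:
    def test_database_count_weights(self):
        hprd = [("g1", "g2"), ("g2", "g3")]
        biogrid = [("g2", "g1"), ("g2", "g1")]  # reversed + duplicated rows
        intact = [("g1", "g2")]
        edges = {(u, v): w for u, v, w in gene_edges([hprd, biogrid, intact])}
        assert edges[("g1", "g2")] == 3.0
        assert edges[("g2", "g3")] == 1.0

    def test_within_database_duplicates_count_once(self):
        edges = gene_edges([[("g1", "g2"), ("g1", "g2")]])
        assert edges == [("g1", "g2", 1.0)]


class TestBuild2hn:
    def test_channels_and_isolated_nodes(self):
        net = build_2hn(
            similarity_edges=[("c1", "c2", 1.0)],
            chem_gene_edges=[("c1", "g1"), ("c2", "g2")],
            gene_edges=[("g1", "g2", 2.0)],
            extra_chemicals=["c9"],
            extra_genes=["g9"],
        )
        assert len(net.nodes_of_class("A")) == 3 and len(net.nodes_of_class("B")) == 3
        counts = {"AA": 0, "AB": 0, "BB": 0}
        for *_, ch in net.edges():
            counts[ch] += 1
        assert counts == {"AA": 1, "AB": 2, "BB": 1}

    def test_empty_similarity_channel_ok(self):
        net = build_2hn([], [("c1", "g1")], [("g1", "g2", 1.0)])
        from mixmod import subnetwork_stats

        assert subnetwork_stats(net).mA == 0.0

    def test_class_clash_rejected(self):
        with pytest.raises(HetNetError):
            build_2hn([("c1", "c2", 1.0)], [("c3", "c1")], [])


class TestCorrelation:
    def test_perfect_monotone_association(self):
        """y strictly increasing in similarity across all pairs -> rho = 1.

        Pairwise similarities: (c1,c3)=4/8 < (c1,c2)=4/6 < (c2,c3)=6/8;
        shared-target counts follow the same strict order: 0 < 1 < 2.
        """
        fps = {
            "c1": as_fingerprint("111100000000"),
            "c2": as_fingerprint("111111000000"),
            "c3": as_fingerprint("111111110000"),
        }
        cg = [("c1", "g1"), ("c2", "g1"), ("c2", "g3"), ("c2", "g4"),
              ("c3", "g3"), ("c3", "g4")]
        net = build_2hn([], cg, [])
        rec = similarity_interaction_correlation(net, fps)
        assert rec["n_pairs"] == 3
        assert rec["rho"] == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        fps = {"c1": as_fingerprint("11"), "c2": as_fingerprint("11")}
        net = build_2hn([("c1", "c2", 1.0)], [("c1", "g1"), ("c2", "g1")], [])
        with pytest.raises(HetNetError):
            similarity_interaction_correlation(net, fps)

    def test_shared_targets_counted(self):
        fps = {
            "c1": as_fingerprint("1100"),
            "c2": as_fingerprint("1110"),
            "c3": as_fingerprint("0011"),
        }
        cg = [("c1", "g1"), ("c2", "g1"), ("c2", "g2"), ("c3", "g3")]
        net = build_2hn([], cg, [])
        with_shared = similarity_interaction_correlation(net, fps, count_shared_targets=True)
        # only the shared-target component varies here
        assert with_shared["rho"] > 0


class TestPermutationTest:
    def test_planted_labels_maximally_significant(self):
        bench = generate_benchmark(BenchmarkSpec(
            NA=40, kA=4, maxkA=8, muA=0.1, NB=60, kB=6, maxkB=12, muB=0.1, p=0.9,
            min_community_A=10, max_community_A=20,
            min_community_B=15, max_community_B=30, seed=4,
        ))
        rec = label_permutation_test(bench.net, bench.labels, n_perm=99, seed=0)
        assert rec["empirical_p"] == pytest.approx(1 / 100)
        assert rec["observed_mQ"] > rec["null_max"]

    def test_shuffled_labels_not_significant(self):
        bench = generate_benchmark(BenchmarkSpec(
            NA=40, kA=4, maxkA=8, muA=0.1, NB=60, kB=6, maxkB=12, muB=0.1, p=0.9,
            min_community_A=10, max_community_A=20,
            min_community_B=15, max_community_B=30, seed=4,
        ))
        hits = 0
        for rep in range(10):
            # a fresh null labeling per repetition: destroy the signal,
            # preserving class-wise label profiles
            rng = random.Random(rep)
            shuffled = {}
            for cls in ("A", "B"):
                group = bench.net.nodes_of_class(cls)
                labs = [bench.labels[n] for n in group]
                rng.shuffle(labs)
                shuffled.update(zip(group, labs))
            rec = label_permutation_test(bench.net, shuffled, n_perm=99, seed=1000 + rep)
            if rec["empirical_p"] >= 0.05:
                hits += 1
        assert hits >= 8  # null labels should rarely look significant

    def test_deterministic(self):
        bench = generate_benchmark(BenchmarkSpec(
            NA=40, kA=4, maxkA=8, NB=60, kB=6, maxkB=12,
            min_community_A=10, max_community_A=20,
            min_community_B=15, max_community_B=30, seed=4,
        ))
        r1 = label_permutation_test(bench.net, bench.labels, n_perm=99, seed=3)
        r2 = label_permutation_test(bench.net, bench.labels, n_perm=99, seed=3)
        assert r1 == r2

    def test_small_n_perm_rejected(self):
        bench = generate_benchmark(BenchmarkSpec(
            NA=40, kA=4, maxkA=8, NB=60, kB=6, maxkB=12,
            min_community_A=10, max_community_A=20,
            min_community_B=15, max_community_B=30, seed=4,
        ))
        with pytest.raises(HetNetError):
            label_permutation_test(bench.net, bench.labels, n_perm=10)


class TestTargetSets:
    def test_targets_collected_from_ab_channel(self):
        net = build_2hn([], [("c1", "g1"), ("c1", "g2"), ("c2", "g2")], [("g1", "g2", 1.0)])
        ts = target_sets(net)
        assert ts["c1"] == {"g1", "g2"} and ts["c2"] == {"g2"}
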