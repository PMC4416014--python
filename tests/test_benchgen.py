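import math
import random
from collections import Counter

import pytest

from mixmod import (
    BenchmarkSpec,
    GenerationError,
    assign_mixed_modules,
    generate_benchmark,
    generate_bipartite_links,
    generate_lfr_subnetwork,
    realized_mixing,
    realized_weighted_mixing,
)
from mixmod.hetnet import subnetwork_stats


class TestLfrSubnetwork:
    @pytest.mark.parametrize("seed", range(5))
    def test_degree_and_mixing_targets(self, seed):
        edges, comm = generate_lfr_subnetwork(400, 4, 16, 0.2, seed=seed)
        deg = Counter()
        for u, v in edges:
            deg[u] += 1
            deg[v] += 1
        mean_deg = sum(deg.values()) / 400
        assert abs(mean_deg - 4) / 4 < 0.10
        assert max(deg.values()) <= 16
        assert abs(realized_mixing(edges, comm) - 0.2) < 0.05

    def test_mu_zero_disconnects_communities(self):
        edges, comm = generate_lfr_subnetwork(100, 4, 10, 0.0, seed=1)
        assert all(comm[u] == comm[v] for u, v in edges)

    def test_community_size_bounds(self):
        _, comm = generate_lfr_subnetwork(400, 4, 16, 0.3, seed=2)
        sizes = Counter(comm).values()
        assert min(sizes) >= 10 and max(sizes) <= 80

    def test_high_mixing_realized(self):
        edges, comm = generate_lfr_subnetwork(600, 12, 48, 0.8, seed=3)
        assert abs(realized_mixing(edges, comm) - 0.8) < 0.05

    def test_infeasible_parameters_error(self):
        with pytest.raises((GenerationError, ValueError)):
            # max degree nearly the node count cannot fit in any community
            generate_lfr_subnetwork(30, 10, 29, 0.0, seed=0, min_community=5, max_community=8)


class TestAssignMixedModules:
    def test_pigeonhole_with_unequal_sides(self):
        out = assign_mixed_modules([0, 1, 2], [0, 1, 2, 3, 4], seed=7)
        mods_a = [out[("A", c)] for c in range(3)]
        assert sorted(mods_a) == [0, 1, 2]  # bijection on the smaller side
        mods_b = {out[("B", c)] for c in range(5)}
        assert mods_b == {0, 1, 2}  # surjection on the larger side

    def test_equal_sides_bijection(self):
        out = assign_mixed_modules([0, 1, 2, 3], [0, 1, 2, 3], seed=1)
        assert sorted(out[("A", c)] for c in range(4)) == [0, 1, 2, 3]
        assert sorted(out[("B", c)] for c in range(4)) == [0, 1, 2, 3]

    def test_uniform_over_valid_assignments(self):
        """nA=2, nB=4: exactly 2 x 14 valid (A-bijection, B-surjection)
        assignments; each B-side surjection pattern should appear with
        its enumerated frequency."""
        counts = Counter()
        n_draws = 3000
        for seed in range(n_draws):
            out = assign_mixed_modules([0, 1], [0, 1, 2, 3], seed=seed)
            # pattern of the B side relative to the module of A community 0
            m0 = out[("A", 0)]
            counts[tuple(1 if out[("B", c)] == m0 else 0 for c in range(4))] += 1
        assert len(counts) == 14  # all surjections of 4 items onto 2 blocks
        expected = n_draws / 14
        for pattern, n in counts.items():
            assert abs(n - expected) < 5 * math.sqrt(expected), (pattern, n)


class TestBipartiteLinks:
    A = [f"a{i}" for i in range(20)]
    B = [f"b{i}" for i in range(30)]
    module_of = {**{a: i % 2 for i, a in enumerate(A)}, **{b: i % 2 for i, b in enumerate(B)}}

    def test_edge_count_exact(self):
        edges = generate_bipartite_links(self.A, self.B, self.module_of, 0.5, 3.0, seed=1)
        assert len(edges) == round(3.0 * len(self.A))
        assert len(set(edges)) == len(edges)  # simple graph

    def test_p_one_all_within_module(self):
        edges = generate_bipartite_links(self.A, self.B, self.module_of, 1.0, 4.0, seed=2)
        assert all(self.module_of[a] == self.module_of[b] for a, b in edges)

    def test_p_zero_matches_baseline_rate(self):
        # expected within-module fraction = sum |Ac||Bc| / (|A||B|) = (10*15)*2/600
        within = 0
        total = 0
        for seed in range(20):
            edges = generate_bipartite_links(self.A, self.B, self.module_of, 0.0, 4.0, seed=seed)
            within += sum(1 for a, b in edges if self.module_of[a] == self.module_of[b])
            total += len(edges)
        assert abs(within / total - 0.5) < 0.05

    def test_capacity_error(self):
        with pytest.raises(GenerationError):
            generate_bipartite_links(self.A[:2], self.B[:2], self.module_of, 0.5, 10.0, seed=0)


class TestGenerateBenchmark:
    def test_default_spec_shape(self):
        bench = generate_benchmark(BenchmarkSpec(seed=5))
        assert len(bench.net.nodes_of_class("A")) == 400
        assert len(bench.net.nodes_of_class("B")) == 600
        st = subnetwork_stats(bench.net)
        assert st.mA > 0 and st.mPi > 0 and st.mB > 0
        assert set(bench.labels) == set(bench.net.nodes)
        # every planted module is mixed
        for m in set(bench.labels.values()):
            members = [n for n, lab in bench.labels.items() if lab == m]
            classes = {bench.net.node_class(n).value for n in members}
            assert classes == {"A", "B"}

    def test_determinism(self):
        b1 = generate_benchmark(BenchmarkSpec(seed=9))
        b2 = generate_benchmark(BenchmarkSpec(seed=9))
        assert b1.net == b2.net and b1.labels == b2.labels

    def test_seeds_differ(self):
        b1 = generate_benchmark(BenchmarkSpec(seed=1))
        b2 = generate_benchmark(BenchmarkSpec(seed=2))
        assert b1.net != b2.net

    @pytest.mark.parametrize("channel,attr", [("GA", "AA"), ("GPi", "AB"), ("GB", "BB")])
    def test_weighted_channel(self, channel, attr):
        """Weighted-LFR scheme: strength ~ degree^beta, weighted mixing ~ muW."""
        mixes = []
        for seed in range(3):
            spec = BenchmarkSpec(seed=seed, weighting=channel, beta=2.0)
            bench = generate_benchmark(spec)
            wmap = {}
            deg = Counter()
            strength = Counter()
            for u, v, w, ch in bench.net.edges():
                if ch == attr:
                    wmap[(u, v)] = w
                    deg[u] += 1
                    deg[v] += 1
                    strength[u] += w
                    strength[v] += w
                else:
                    assert w == 1.0  # other channels stay unweighted
            # per-node strength tracks degree^2
            ratios = [strength[n] / deg[n] ** 2 for n in deg]
            assert 0.7 < sum(ratios) / len(ratios) < 1.3
            mixes.append(realized_weighted_mixing(wmap, bench.labels))
        target = {"GA": 0.2, "GPi": 0.5, "GB": 0.2}[channel]
        assert abs(sum(mixes) / len(mixes) - target) < 0.05

    def test_realized_mixing_at_defaults(self):
        """Topological mixing of both LFR sides within +-0.05, 10 seeds."""
        muAs, muBs = [], []
        for seed in range(10):
            ea, ca = generate_lfr_subnetwork(400, 4, 16, 0.2, seed=seed * 3 + 1)
            eb, cb = generate_lfr_subnetwork(600, 12, 48, 0.2, seed=seed * 3 + 2)
            muAs.append(realized_mixing(ea, ca))
            muBs.append(realized_mixing(eb, cb))
        assert abs(sum(muAs) / 10 - 0.2) < 0.05
        assert abs(sum(muBs) / 10 - 0.2) < 0.05

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            BenchmarkSpec(muA=1.5)
        with pytest.raises(ValueError):
            BenchmarkSpec(kA=20, maxkA=16)
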