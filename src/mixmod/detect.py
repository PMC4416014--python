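"""MixMod: Louvain-style optimization of mixed modularity on a 2-HN.

The search alternates two phases.  Phase one sweeps nodes in (seeded)
random order and greedily moves each node to the neighboring module
with the largest strictly positive gain in mixed modularity, repeating
until a full sweep makes no move.  Phase two aggregates the partition
into a coarse 2-HN: each module becomes up to two class-pure supernodes
(its A-side and B-side submodules), internal submodule weight becomes a
supernode self-loop, and inter-submodule weights are summed.  Keeping
the supernodes class-pure means the coarse graph is again a valid 2-HN
and the same quality function applies unchanged at every level; at the
start of the next level the two supernodes of each module are
co-assigned, which preserves mQ exactly across the aggregation.

Self-loop convention in coarse graphs: a self-loop of weight w counts
w toward its channel total and 2w toward its node's degree.  This is
what makes mQ of the coarse graph equal mQ of the fine graph under the
lineage-induced partition.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .hetnet import HetNet, NodeClass, Partition
from .modularity import mixed_modularity


@dataclass
class DetectConfig:
    """Knobs of the MixMod search.

    ``seed`` drives the per-sweep node shuffle, ``min_gain`` is the
    minimum total mQ improvement a level must deliver for the search to
    continue, and ``node_order`` chooses between seeded shuffling and
    the network's input order.
    """

    seed: int = 0
    max_levels: int = 20
    min_gain: float = 1e-9
    node_order: str = "shuffled"  # or "input"

    def __post_init__(self) -> None:
        if self.max_levels < 1:
            raise ValueError("max_levels must be >= 1")
        if self.min_gain < 0:
            raise ValueError("min_gain must be >= 0")
        if self.node_order not in ("shuffled", "input"):
            raise ValueError("node_order must be 'shuffled' or 'input'")


@dataclass
class DetectResult:
    partition: Partition
    mQ: float
    n_modules: int
    n_mixed_modules: int
    levels: int
    per_level_mQ: list[float] = field(default_factory=list)


class _State:
    """Channel-separated bookkeeping for one level's local-moving phase."""

    def __init__(self, net: HetNet, init: Partition):
        self.nodes = list(net.nodes)
        self.cls = {n: net.node_class(n) for n in self.nodes}
        # adjacency split by channel: same-class channel vs bipartite
        self.adj_same: dict[str, dict[str, float]] = {n: {} for n in self.nodes}
        self.adj_pi: dict[str, dict[str, float]] = {n: {} for n in self.nodes}
        self.deg_same = {n: 0.0 for n in self.nodes}  # dA for A nodes, dB for B nodes
        self.deg_pi = {n: 0.0 for n in self.nodes}  # kPi for A nodes, dPi for B nodes
        self.mA = self.mPi = self.mB = 0.0
        for u, v, w, ch in net.edges():
            if ch == "AA":
                self.mA += w
            elif ch == "BB":
                self.mB += w
            else:
                self.mPi += w
            if ch == "AB":
                self.adj_pi[u][v] = self.adj_pi[u].get(v, 0.0) + w
                self.adj_pi[v][u] = self.adj_pi[v].get(u, 0.0) + w
                self.deg_pi[u] += w
                self.deg_pi[v] += w
            elif u == v:
                self.deg_same[u] += 2 * w  # self-loop: excluded from adj, degree 2w
            else:
                self.adj_same[u][v] = self.adj_same[u].get(v, 0.0) + w
                self.adj_same[v][u] = self.adj_same[v].get(u, 0.0) + w
                self.deg_same[u] += w
                self.deg_same[v] += w
        self.assign = dict(init.assignment)
        # per-module degree sums, kept separately per class and channel
        self.DA: dict[int, float] = {}
        self.KPi: dict[int, float] = {}
        self.DPi: dict[int, float] = {}
        self.DB: dict[int, float] = {}
        for n in self.nodes:
            self._insert(n, self.assign[n])

    def _insert(self, n: str, m: int) -> None:
        if self.cls[n] == NodeClass.A:
            self.DA[m] = self.DA.get(m, 0.0) + self.deg_same[n]
            self.KPi[m] = self.KPi.get(m, 0.0) + self.deg_pi[n]
        else:
            self.DB[m] = self.DB.get(m, 0.0) + self.deg_same[n]
            self.DPi[m] = self.DPi.get(m, 0.0) + self.deg_pi[n]

    def _remove(self, n: str, m: int) -> None:
        if self.cls[n] == NodeClass.A:
            self.DA[m] -= self.deg_same[n]
            self.KPi[m] -= self.deg_pi[n]
        else:
            self.DB[m] -= self.deg_same[n]
            self.DPi[m] -= self.deg_pi[n]

    def placement_score(self, n: str, m: int, w_same: float, w_pi: float) -> float:
        """Score (3x the mQ contribution, up to node-constant terms) of
        placing ``n`` into module ``m``, with ``n`` currently removed."""
        s = 0.0
        if self.cls[n] == NodeClass.A:
            if self.mA > 0:
                s += w_same / self.mA - self.deg_same[n] * (
                    2 * self.DA.get(m, 0.0) + self.deg_same[n]
                ) / (4 * self.mA**2)
            if self.mPi > 0:
                s += w_pi / self.mPi - self.deg_pi[n] * self.DPi.get(m, 0.0) / self.mPi**2
        else:
            if self.mB > 0:
                s += w_same / self.mB - self.deg_same[n] * (
                    2 * self.DB.get(m, 0.0) + self.deg_same[n]
                ) / (4 * self.mB**2)
            if self.mPi > 0:
                s += w_pi / self.mPi - self.deg_pi[n] * self.KPi.get(m, 0.0) / self.mPi**2
        return s


def local_moving_pass(
    net: HetNet,
    partition: Partition,
    config: DetectConfig,
    rng: random.Random | None = None,
) -> tuple[Partition, float]:
    """Phase one: greedy node moves until a full sweep changes nothing.

    Each node is offered every module adjacent to it through any
    channel; it takes the first move with maximal, strictly positive
    gain (ties keep the earlier candidate; staying put wins ties too).
    Returns the stabilized partition and the total mQ gain (>= 0).
    """
    partition.require_covers(net)
    if rng is None:
        rng = random.Random(config.seed)
    state = _State(net, partition)
    order = list(state.nodes)
    total_gain = 0.0
    moved = True
    while moved:
        moved = False
        if config.node_order == "shuffled":
            rng.shuffle(order)
        for n in order:
            c = state.assign[n]
            # neighbor-module link weights, per channel
            w_same: dict[int, float] = {}
            w_pi: dict[int, float] = {}
            for nb, w in state.adj_same[n].items():
                m = state.assign[nb]
                w_same[m] = w_same.get(m, 0.0) + w
            for nb, w in state.adj_pi[n].items():
                m = state.assign[nb]
                w_pi[m] = w_pi.get(m, 0.0) + w
            state._remove(n, c)
            best_m = c
            best_s = state.placement_score(n, c, w_same.get(c, 0.0), w_pi.get(c, 0.0))
            stay_s = best_s
            for m in list(w_same) + [m for m in w_pi if m not in w_same]:
                if m == c:
                    continue
                s = state.placement_score(n, m, w_same.get(m, 0.0), w_pi.get(m, 0.0))
                if s > best_s:
                    best_s, best_m = s, m
            state._insert(n, best_m)
            if best_m != c:
                state.assign[n] = best_m
                total_gain += (best_s - stay_s) / 3.0
                moved = True
    return Partition(state.assign), total_gain


def aggregate(net: HetNet, partition: Partition) -> tuple[HetNet, dict[str, int]]:
    """Phase two: collapse each module into class-pure supernodes.

    Returns the coarse 2-HN (with self-loops) and a lineage map
    supernode id -> module id of the fine partition.
    """
    partition.require_covers(net)
    part = Partition(partition.assignment)  # canonical contiguous ids
    sn_nodes: dict[str, NodeClass] = {}
    lineage: dict[str, int] = {}
    for nid, cls in net.nodes.items():
        m = part[nid]
        sn = f"{m}{cls.value}"
        if sn not in sn_nodes:
            sn_nodes[sn] = cls
            lineage[sn] = m
    weights: dict[tuple[str, str], float] = {}
    for u, v, w, _ in net.edges():
        su = f"{part[u]}{net.node_class(u).value}"
        sv = f"{part[v]}{net.node_class(v).value}"
        key = (su, sv) if su <= sv else (sv, su)
        weights[key] = weights.get(key, 0.0) + w
    coarse = HetNet(sn_nodes, allow_self_loops=True)
    for (su, sv), w in weights.items():
        coarse.add_edge(su, sv, w)
    return coarse, lineage


def classify_modules(net: HetNet, partition: Partition) -> dict[int, str]:
    """Label each module ``mixed``, ``A_only`` or ``B_only``.

    A module is mixed iff it contains at least one node of each class;
    single-class modules are the degenerate case that contributes to mQ
    only through its own channel.
    """
    partition.require_covers(net)
    has_a: set[int] = set()
    has_b: set[int] = set()
    for nid, cls in net.nodes.items():
        (has_a if cls == NodeClass.A else has_b).add(partition[nid])
    out = {}
    for m in set(partition.assignment.values()):
        if m in has_a and m in has_b:
            out[m] = "mixed"
        elif m in has_a:
            out[m] = "A_only"
        else:
            out[m] = "B_only"
    return out


def mixmod_detect(net: HetNet, config: DetectConfig | None = None) -> DetectResult:
    """Run the full two-phase MixMod search on a 2-HN.

    Levels of local moving + aggregation repeat until a level improves
    mQ by less than ``config.min_gain``, aggregation stops shrinking the
    graph, or ``config.max_levels`` is reached.  The reported partition
    is projected back to the original nodes and its mQ recomputed on the
    original network.
    """
    if config is None:
        config = DetectConfig()
    if net.n_edges == 0:
        partition = Partition.singletons(net)
        kinds = classify_modules(net, partition)
        return DetectResult(
            partition=partition,
            mQ=0.0,
            n_modules=partition.n_modules,
            n_mixed_modules=0,
            levels=0,
            per_level_mQ=[],
        )
    rng = random.Random(config.seed)
    current = net
    to_current: dict[str, str] = {n: n for n in net.nodes}  # original -> current-level node
    init = Partition.singletons(current)
    per_level_mQ: list[float] = []
    best_assign = {n: init[to_current[n]] for n in net.nodes}
    levels = 0
    for _ in range(config.max_levels):
        part, gain = local_moving_pass(current, init, config, rng)
        levels += 1
        best_assign = {n: part[to_current[n]] for n in net.nodes}
        per_level_mQ.append(mixed_modularity(net, Partition(best_assign)))
        if gain < config.min_gain:
            break
        coarse, lineage = aggregate(current, part)
        if coarse.n_nodes == current.n_nodes:
            break
        canon = Partition(part.assignment)
        to_current = {
            n: f"{canon[to_current[n]]}{net.node_class(n).value}" for n in net.nodes
        }
        current = coarse
        init = Partition({sn: m for sn, m in lineage.items()}, canonicalize=False)
    # polish at the finest level so the result is a true local optimum
    # (coarse-level stability does not imply single-node stability below)
    polished, gain = local_moving_pass(net, Partition(best_assign), config, rng)
    if gain > 0:
        per_level_mQ.append(mixed_modularity(net, polished))
        levels += 1
    partition = Partition(polished.assignment)
    kinds = classify_modules(net, partition)
    return DetectResult(
        partition=partition,
        mQ=mixed_modularity(net, partition),
        n_modules=partition.n_modules,
        n_mixed_modules=sum(1 for k in kinds.values() if k == "mixed"),
        levels=levels,
        per_level_mQ=per_level_mQ,
    )
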