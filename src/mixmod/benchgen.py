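"""Labeled benchmark 2-HNs with planted mixed modules.

The generator follows a five-step recipe: (1) build the A-side
subnetwork as an LFR-style graph -- power-law degree sequence with mean
``kA`` and cutoff ``maxkA``, power-law community sizes, and a mixing
parameter ``muA`` giving the fraction of each node's edges that leave
its community; (2) likewise for the B side; (3) group the A communities
and B communities into ``nc = min(nA, nB)`` planted mixed modules,
uniformly at random subject to every module receiving at least one
community from each side; (4) draw ``round(kPi * NA)`` bipartite edges,
each placed inside a planted module with probability ``p`` (the module
chosen proportional to its A x B pair count) and between arbitrary
endpoints otherwise; (5) emit the integrated 2-HN with a planted
mixed-module label per node.

The LFR wiring is done with per-community and global configuration
models on the internal/external stub counts ``round((1-mu) d)`` and the
remainder, so the realized mixing tracks the requested value closely.
Optionally one channel is weighted following the weighted-LFR scheme:
target node strength ``d^beta``, of which a fraction ``1 - muw`` is
carried by intra-module edges.
"""

from __future__ import annotations

import bisect
import random
from dataclasses import dataclass, field
from functools import lru_cache

from .hetnet import HetNet


class GenerationError(RuntimeError):
    """Raised when a feasible benchmark cannot be drawn within the retry budget."""


_MAX_RETRIES = 100


@dataclass
class BenchmarkSpec:
    """All parameters of the benchmark generator.

    Defaults are the study's standard configuration: a 400-node A side
    (mean degree 4, max 16) and a 600-node B side (mean degree 12, max
    48), mixing 0.2 on both sides, bipartite coupling p = 0.5 and mean
    bipartite degree 4 per A node.  ``tau1``/``tau2`` are the power-law
    exponents of the degree and community-size distributions.
    ``weighting`` selects at most one channel to weight (``none``,
    ``GA``, ``GPi`` or ``GB``) with strength exponent ``beta`` and
    weight-mixing ``muW`` (``None`` = the channel's own topological
    mixing: muA, 1 - p or muB).
    """

    NA: int = 400
    kA: float = 4.0
    maxkA: int = 16
    muA: float = 0.2
    NB: int = 600
    kB: float = 12.0
    maxkB: int = 48
    muB: float = 0.2
    p: float = 0.5
    kPi: float = 4.0
    tau1: float = 2.0
    tau2: float = 1.0
    weighting: str = "none"
    beta: float = 2.0
    muW: float | None = None
    seed: int = 0
    min_community_A: int | None = None
    max_community_A: int | None = None
    min_community_B: int | None = None
    max_community_B: int | None = None

    def __post_init__(self) -> None:
        for name in ("muA", "muB", "p"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.muW is not None and not 0 <= self.muW <= 1:
            raise ValueError("muW must be in [0, 1]")
        if not self.kA <= self.maxkA < self.NA:
            raise ValueError("need kA <= maxkA < NA")
        if not self.kB <= self.maxkB < self.NB:
            raise ValueError("need kB <= maxkB < NB")
        if self.weighting not in ("none", "GA", "GPi", "GB"):
            raise ValueError("weighting must be none, GA, GPi or GB")
        if self.kPi <= 0:
            raise ValueError("kPi must be > 0")


@dataclass
class LabeledHetNet:
    """A generated 2-HN plus its planted mixed-module label per node."""

    net: HetNet
    labels: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------
# power-law sampling helpers
# ---------------------------------------------------------------------

def _powerlaw_cdf(exponent: float, lo: int, hi: int) -> tuple[list[int], list[float]]:
    support = list(range(lo, hi + 1))
    probs = [x ** (-exponent) for x in support]
    total = sum(probs)
    cum, acc = [], 0.0
    for pr in probs:
        acc += pr / total
        cum.append(acc)
    return support, cum


def _draw_powerlaw(rng: random.Random, support: list[int], cum: list[float]) -> int:
    return support[bisect.bisect_left(cum, rng.random())]


def _powerlaw_mean(exponent: float, lo: int, hi: int) -> float:
    num = sum(x ** (1 - exponent) for x in range(lo, hi + 1))
    den = sum(x ** (-exponent) for x in range(lo, hi + 1))
    return num / den


def _degree_sequence(N: int, k: float, maxk: int, tau1: float, rng: random.Random) -> list[int]:
    """Power-law degrees with empirical mean pinned to ``k``.

    The lower cutoff is chosen so the distribution's mean is closest to
    ``k``; the sampled sequence is then nudged by unit steps to make the
    total hit ``round(N * k)`` (kept even for stub pairing downstream).
    """
    lo = min(
        range(1, maxk + 1),
        key=lambda c: abs(_powerlaw_mean(tau1, c, maxk) - k),
    )
    support, cum = _powerlaw_cdf(tau1, lo, maxk)
    degs = [_draw_powerlaw(rng, support, cum) for _ in range(N)]
    target = round(N * k)
    if target % 2:
        target += 1
    guard = 0
    while sum(degs) != target:
        i = rng.randrange(N)
        if sum(degs) > target and degs[i] > max(1, lo - 1):
            degs[i] -= 1
        elif sum(degs) < target and degs[i] < maxk:
            degs[i] += 1
        guard += 1
        if guard > 100 * N:
            raise GenerationError("cannot adjust degree sequence to target mean")
    return degs


def _community_sizes(N: int, minc: int, maxc: int, tau2: float, rng: random.Random) -> list[int]:
    if minc > N:
        raise GenerationError("min community size exceeds node count")
    support, cum = _powerlaw_cdf(tau2, minc, min(maxc, N))
    for _ in range(_MAX_RETRIES):
        sizes: list[int] = []
        while sum(sizes) < N:
            sizes.append(_draw_powerlaw(rng, support, cum))
        excess = sum(sizes) - N
        guard = 0
        while excess > 0 and guard < 100 * len(sizes):
            i = rng.randrange(len(sizes))
            if sizes[i] > minc:
                sizes[i] -= 1
                excess -= 1
            guard += 1
        if excess == 0:
            return sizes
    raise GenerationError("cannot draw community sizes summing to N")


def _assign_communities(
    dint: list[int], sizes: list[int], rng: random.Random
) -> list[int]:
    """Place each node in a community larger than its internal degree."""
    order = sorted(range(len(dint)), key=lambda i: -dint[i])
    for _ in range(_MAX_RETRIES):
        remaining = list(sizes)
        comm = [-1] * len(dint)
        ok = True
        for i in order:
            feas = [c for c in range(len(sizes)) if remaining[c] > 0 and sizes[c] > dint[i]]
            if not feas:
                ok = False
                break
            weights = [remaining[c] for c in feas]
            comm[i] = rng.choices(feas, weights=weights)[0]
            remaining[comm[i]] -= 1
        if ok:
            return comm
    raise GenerationError(
        "cannot fit internal degrees into community sizes "
        "(smallest feasible community < maxk * (1 - mu))"
    )


def _pair_stubs(
    stubs: list[int],
    rng: random.Random,
    *,
    forbidden_same: list[int] | None = None,
) -> list[tuple[int, int]]:
    """Configuration-model pairing yielding a simple graph.

    ``forbidden_same``: optional community label per node; pairs inside
    one community are disallowed (used for the external wiring).
    Conflicting pairs are repaired by random edge swaps; the few that
    cannot be repaired are dropped.
    """
    stubs = list(stubs)
    rng.shuffle(stubs)
    pairs = [(stubs[i], stubs[i + 1]) for i in range(0, len(stubs) - 1, 2)]

    def bad(u: int, v: int, seen: set[tuple[int, int]]) -> bool:
        if u == v:
            return True
        if forbidden_same is not None and forbidden_same[u] == forbidden_same[v]:
            return True
        return (min(u, v), max(u, v)) in seen

    for _ in range(10):  # repair passes
        seen: set[tuple[int, int]] = set()
        conflicts: list[int] = []
        for idx, (u, v) in enumerate(pairs):
            if bad(u, v, seen):
                conflicts.append(idx)
            else:
                seen.add((min(u, v), max(u, v)))
        if not conflicts:
            break
        for idx in conflicts:
            u, v = pairs[idx]
            for _ in range(50):
                j = rng.randrange(len(pairs))
                if j == idx:
                    continue
                x, y = pairs[j]
                # swap partners: (u,v),(x,y) -> (u,y),(x,v)
                key_uy = (min(u, y), max(u, y))
                key_xv = (min(x, v), max(x, v))
                if bad(u, y, seen) or bad(x, v, seen) or key_uy == key_xv:
                    continue
                if (min(x, y), max(x, y)) in seen:
                    seen.discard((min(x, y), max(x, y)))
                pairs[idx] = (u, y)
                pairs[j] = (x, v)
                seen.add(key_uy)
                seen.add(key_xv)
                break
    # final sweep: drop anything still conflicting
    seen = set()
    out = []
    for u, v in pairs:
        if bad(u, v, seen):
            continue
        seen.add((min(u, v), max(u, v)))
        out.append((u, v))
    return out


def generate_lfr_subnetwork(
    N: int,
    k: float,
    maxk: int,
    mu: float,
    tau1: float = 2.0,
    tau2: float = 1.0,
    seed: int = 0,
    min_community: int | None = None,
    max_community: int | None = None,
) -> tuple[list[tuple[int, int]], list[int]]:
    """One LFR-style single-class subnetwork.

    Returns the edge list over nodes ``0..N-1`` and a community label
    per node.  Each node sends ``round((1 - mu) d)`` of its ``d`` edges
    inside its community and the rest across community borders.
    """
    if not 0 <= mu <= 1:
        raise ValueError("mu must be in [0, 1]")
    if not k <= maxk < N:
        raise ValueError("need k <= maxk < N")
    if min_community is None:
        min_community = max(10, maxk // 2)
    if max_community is None:
        max_community = max(N // 5, min_community)
    last_err: Exception | None = None
    for attempt in range(_MAX_RETRIES):
        rng = random.Random(f"{seed}:{attempt}")
        try:
            degs = _degree_sequence(N, k, maxk, tau1, rng)
            # stochastic rounding keeps E[internal degree] = (1-mu) d exactly,
            # so the realized mixing is unbiased even at small degrees
            dint = []
            for d in degs:
                x = (1 - mu) * d
                base = int(x)
                dint.append(base + (1 if rng.random() < x - base else 0))
            sizes = _community_sizes(N, min_community, max_community, tau2, rng)
            comm = _assign_communities(dint, sizes, rng)
            edges: list[tuple[int, int]] = []
            # internal wiring, one configuration model per community
            for c in range(len(sizes)):
                members = [i for i in range(N) if comm[i] == c]
                stubs: list[int] = []
                counts = {i: dint[i] for i in members}
                if sum(counts.values()) % 2:
                    # drop one stub from the member with the most to spare
                    i = max(members, key=lambda i: counts[i])
                    counts[i] -= 1
                for i in members:
                    stubs.extend([i] * counts[i])
                edges.extend(_pair_stubs(stubs, rng))
            # external wiring, global configuration model
            stubs = []
            for i in range(N):
                stubs.extend([i] * (degs[i] - dint[i]))
            if len(stubs) % 2:
                stubs.pop(rng.randrange(len(stubs)))
            internal_seen = {(min(u, v), max(u, v)) for u, v in edges}
            ext = _pair_stubs(stubs, rng, forbidden_same=comm)
            edges.extend(e for e in ext if (min(e), max(e)) not in internal_seen)
            return edges, comm
        except GenerationError as err:
            last_err = err
    raise GenerationError(f"LFR generation failed after {_MAX_RETRIES} attempts: {last_err}")


# ---------------------------------------------------------------------
# step 3: grouping communities into mixed modules
# ---------------------------------------------------------------------

@lru_cache(maxsize=None)
def _stirling2(n: int, kk: int) -> int:
    if kk == 0:
        return 1 if n == 0 else 0
    if n < kk:
        return 0
    if n == kk or kk == 1:
        return 1
    return _stirling2(n - 1, kk - 1) + kk * _stirling2(n - 1, kk)


def _uniform_set_partition(n: int, kk: int, rng: random.Random) -> list[int]:
    """Uniform partition of items 0..n-1 into exactly ``kk`` unlabeled blocks."""
    decisions: list[bool] = []  # True: item founds its own block
    nn, rem = n, kk
    while nn > 0:
        if rng.randrange(_stirling2(nn, rem)) < _stirling2(nn - 1, rem - 1):
            decisions.append(True)
            rem -= 1
        else:
            decisions.append(False)
        nn -= 1
    # decisions[j] belongs to item n-1-j; rebuild bottom-up from item 0
    blocks: list[list[int]] = []
    for item in range(n):
        if decisions[n - 1 - item]:
            blocks.append([item])
        else:
            blocks[rng.randrange(len(blocks))].append(item)
    return _blocks_to_labels(blocks, n)


def _blocks_to_labels(blocks: list[list[int]], n: int) -> list[int]:
    lab = [0] * n
    for b, items in enumerate(blocks):
        for i in items:
            lab[i] = b
    return lab


def assign_mixed_modules(
    labelsA: list[int], labelsB: list[int], seed: int = 0
) -> dict[tuple[str, int], int]:
    """Group the A and B communities into ``nc = min(nA, nB)`` mixed modules.

    The assignment is uniform over all groupings in which every mixed
    module receives at least one community from each side: the side
    with exactly ``nc`` communities is matched to modules by a random
    bijection, the other side by a uniformly random surjection (sampled
    exactly via a Stirling-number recursion).  Returns a map
    ``(class, community_id) -> module_id`` with class in ``{"A", "B"}``.
    """
    rng = random.Random(f"{seed}:assign")
    commsA = sorted(set(labelsA))
    commsB = sorted(set(labelsB))
    if not commsA or not commsB:
        raise ValueError("both sides need at least one community")
    nc = min(len(commsA), len(commsB))

    def side_assignment(comms: list[int]) -> dict[int, int]:
        if len(comms) == nc:
            mods = list(range(nc))
            rng.shuffle(mods)
            return dict(zip(comms, mods))
        lab = _uniform_set_partition(len(comms), nc, rng)
        mods = list(range(nc))
        rng.shuffle(mods)
        return {c: mods[lab[i]] for i, c in enumerate(comms)}

    out: dict[tuple[str, int], int] = {}
    for c, m in side_assignment(commsA).items():
        out[("A", c)] = m
    for c, m in side_assignment(commsB).items():
        out[("B", c)] = m
    return out


# ---------------------------------------------------------------------
# step 4: bipartite wiring
# ---------------------------------------------------------------------

def generate_bipartite_links(
    A_nodes: list[str],
    B_nodes: list[str],
    module_of: dict[str, int],
    p: float,
    kPi: float,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Draw ``round(kPi * |A|)`` bipartite edges.

    Each edge falls inside one planted mixed module with probability
    ``p`` (module chosen proportional to its A x B pair count, endpoints
    uniform within it) and between arbitrary A/B endpoints otherwise.
    Duplicates are resampled.
    """
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    rng = random.Random(f"{seed}:bipartite")
    n_edges = round(kPi * len(A_nodes))
    if n_edges > len(A_nodes) * len(B_nodes):
        raise GenerationError("requested bipartite edges exceed simple-graph capacity")
    by_mod_A: dict[int, list[str]] = {}
    by_mod_B: dict[int, list[str]] = {}
    for a in A_nodes:
        by_mod_A.setdefault(module_of[a], []).append(a)
    for b in B_nodes:
        by_mod_B.setdefault(module_of[b], []).append(b)
    mods = [m for m in by_mod_A if m in by_mod_B]
    pair_counts = [len(by_mod_A[m]) * len(by_mod_B[m]) for m in mods]
    if p > 0 and not mods:
        raise GenerationError("no module contains both classes; cannot place within-module links")
    cum, acc = [], 0
    for pc in pair_counts:
        acc += pc
        cum.append(acc)
    seen: set[tuple[str, str]] = set()
    edges: list[tuple[str, str]] = []
    attempts = 0
    budget = max(10_000, 200 * n_edges)
    while len(edges) < n_edges:
        attempts += 1
        if attempts > budget:
            raise GenerationError("bipartite edge resampling budget exhausted")
        if rng.random() < p:
            m = mods[bisect.bisect_left(cum, rng.randrange(acc) + 1)] if acc else mods[0]
            a = rng.choice(by_mod_A[m])
            b = rng.choice(by_mod_B[m])
        else:
            a = rng.choice(A_nodes)
            b = rng.choice(B_nodes)
        if (a, b) in seen:
            continue
        seen.add((a, b))
        edges.append((a, b))
    return edges


# ---------------------------------------------------------------------
# weighted-LFR weighting of one channel
# ---------------------------------------------------------------------

def _weight_channel(
    edges: list[tuple[str, str]],
    is_internal: dict[tuple[str, str], bool],
    beta: float,
    muw: float,
) -> dict[tuple[str, str], float]:
    """Weighted-LFR weights: node strength ~ d^beta, internal share 1 - muw.

    Internal and external edges are weighted separately.  Each starts
    from the mean of its endpoints' per-edge target shares and is then
    refined by multiplicative proportional fitting so that every node's
    realized internal/external strength approaches its target
    ((1-muw) d^beta and muw d^beta respectively).
    """
    deg: dict[str, int] = {}
    for e in edges:
        for v in e:
            deg[v] = deg.get(v, 0) + 1
    target: dict[tuple[str, bool], float] = {}
    for v, d in deg.items():
        s = float(d) ** beta
        target[(v, True)] = (1 - muw) * s
        target[(v, False)] = muw * s
    weights: dict[tuple[str, str], float] = {}
    part_deg: dict[tuple[str, bool], int] = {}
    for e in edges:
        for v in e:
            key = (v, is_internal[e])
            part_deg[key] = part_deg.get(key, 0) + 1
    for e in edges:
        part = is_internal[e]
        shares = [
            target[(v, part)] / part_deg[(v, part)]
            for v in e
            if target[(v, part)] > 0
        ]
        weights[e] = max(sum(shares) / len(shares) if shares else 0.0, 1e-9)
    for _ in range(25):  # proportional fitting toward the strength targets
        strength: dict[tuple[str, bool], float] = {}
        for e, w in weights.items():
            part = is_internal[e]
            for v in e:
                key = (v, part)
                strength[key] = strength.get(key, 0.0) + w
        for e in list(weights):
            part = is_internal[e]
            factors = [
                target[(v, part)] / strength[(v, part)]
                for v in e
                if strength[(v, part)] > 0 and target[(v, part)] > 0
            ]
            if factors:
                weights[e] = max(weights[e] * sum(factors) / len(factors), 1e-12)
    return weights


# ---------------------------------------------------------------------
# step 5: the full generator
# ---------------------------------------------------------------------

def generate_benchmark(spec: BenchmarkSpec) -> LabeledHetNet:
    """Run the five generation steps and integrate the labeled 2-HN."""
    edgesA, commA = generate_lfr_subnetwork(
        spec.NA, spec.kA, spec.maxkA, spec.muA, spec.tau1, spec.tau2,
        seed=spec.seed * 3 + 1,
        min_community=spec.min_community_A, max_community=spec.max_community_A,
    )
    edgesB, commB = generate_lfr_subnetwork(
        spec.NB, spec.kB, spec.maxkB, spec.muB, spec.tau1, spec.tau2,
        seed=spec.seed * 3 + 2,
        min_community=spec.min_community_B, max_community=spec.max_community_B,
    )
    grouping = assign_mixed_modules(commA, commB, seed=spec.seed)
    a_ids = [f"a{i}" for i in range(spec.NA)]
    b_ids = [f"b{i}" for i in range(spec.NB)]
    labels: dict[str, int] = {}
    for i, aid in enumerate(a_ids):
        labels[aid] = grouping[("A", commA[i])]
    for i, bid in enumerate(b_ids):
        labels[bid] = grouping[("B", commB[i])]
    pi_edges = generate_bipartite_links(a_ids, b_ids, labels, spec.p, spec.kPi, seed=spec.seed)

    ea = [(a_ids[u], a_ids[v]) for u, v in edgesA]
    eb = [(b_ids[u], b_ids[v]) for u, v in edgesB]
    wA: dict[tuple[str, str], float] = {}
    wB: dict[tuple[str, str], float] = {}
    wPi: dict[tuple[str, str], float] = {}
    if spec.weighting != "none":
        chan_edges = {"GA": ea, "GB": eb, "GPi": pi_edges}[spec.weighting]
        muw = spec.muW
        if muw is None:
            muw = {"GA": spec.muA, "GB": spec.muB, "GPi": 1 - spec.p}[spec.weighting]
        internal = {e: labels[e[0]] == labels[e[1]] for e in chan_edges}
        wmap = _weight_channel(chan_edges, internal, spec.beta, muw)
        if spec.weighting == "GA":
            wA = wmap
        elif spec.weighting == "GB":
            wB = wmap
        else:
            wPi = wmap

    nodes = {a: "A" for a in a_ids}
    nodes.update({b: "B" for b in b_ids})
    net = HetNet(nodes)
    for e in ea:
        net.add_edge(*e, wA.get(e, 1.0))
    for e in pi_edges:
        net.add_edge(*e, wPi.get(e, 1.0))
    for e in eb:
        net.add_edge(*e, wB.get(e, 1.0))
    return LabeledHetNet(net=net, labels=labels)


# ---------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------

def realized_mixing(edges: list[tuple[int, int]] | list[tuple[str, str]], labels) -> float:
    """Mean over nodes of the fraction of incident edges leaving the
    node's community (unweighted edges; the topological mixing)."""
    deg: dict = {}
    ext: dict = {}
    for u, v in edges:
        for x in (u, v):
            deg[x] = deg.get(x, 0) + 1
        if labels[u] != labels[v]:
            ext[u] = ext.get(u, 0) + 1
            ext[v] = ext.get(v, 0) + 1
    fracs = [ext.get(x, 0) / d for x, d in deg.items() if d > 0]
    return sum(fracs) / len(fracs) if fracs else 0.0


def realized_weighted_mixing(
    edges: dict[tuple[str, str], float], labels: dict[str, int]
) -> float:
    """Mean over nodes of external strength / total strength."""
    s: dict[str, float] = {}
    s_ext: dict[str, float] = {}
    for (u, v), w in edges.items():
        for x in (u, v):
            s[x] = s.get(x, 0.0) + w
        if labels[u] != labels[v]:
            s_ext[u] = s_ext.get(u, 0.0) + w
            s_ext[v] = s_ext.get(v, 0.0) + w
    fracs = [s_ext.get(x, 0.0) / t for x, t in s.items() if t > 0]
    return sum(fracs) / len(fracs) if fracs else 0.0
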