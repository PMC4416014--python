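"""Mixed modularity for 2-class heterogeneous networks.

The quality of a partition of a 2-HN is scored per module and per edge
channel.  Each module ``c`` is virtually split into three submodules --
its A-A part, its bipartite A-B part and its B-B part -- and each part
is scored inside its own subnetwork:

    mQ = (1/3) * sum_c { [lA_c/mA - (dA_c / 2 mA)^2]
                       + [lPi_c/mPi - kPi_c * dPi_c / mPi^2]
                       + [lB_c/mB - (dB_c / 2 mB)^2] }

where ``lX_c`` is the internal weight of module ``c`` in channel X,
``mX`` the channel's total weight, ``dA_c``/``dB_c`` the summed
within-channel degrees of the module's members, and ``kPi_c`` /
``dPi_c`` the summed bipartite degrees of its A and B members.  The AA
and BB terms are Newman-Girvan modularity on the two within-class
subnetworks; the middle term is Barber modularity on the bipartite
subnetwork; mQ is their arithmetic mean over the shared partition.

Weighted networks use weighted degrees (strengths) throughout; an
unweighted network is the special case of all weights equal to 1.  A
channel with zero total weight contributes 0 for every module (the
limit of the term as the channel empties).  Because every term is
normalized by its own channel total, mQ is invariant under any positive
rescaling of the weights of a single channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .hetnet import HetNet, HetNetError, NodeClass, Partition, SubnetworkStats, subnetwork_stats


@dataclass
class ModuleStats:
    """Per-module internal weights and degree sums, per channel.

    Keys are module ids; missing keys mean zero.  ``lA``/``lPi``/``lB``
    are internal edge weights (a self-loop counts once), ``dA``/``dB``
    summed within-class degrees, ``kPi`` summed bipartite degrees of A
    members and ``dPi`` of B members.
    """

    lA: dict[int, float] = field(default_factory=dict)
    lPi: dict[int, float] = field(default_factory=dict)
    lB: dict[int, float] = field(default_factory=dict)
    dA: dict[int, float] = field(default_factory=dict)
    kPi: dict[int, float] = field(default_factory=dict)
    dPi: dict[int, float] = field(default_factory=dict)
    dB: dict[int, float] = field(default_factory=dict)
    n_modules: int = 0


def module_stats(net: HetNet, partition: Partition, subnet: SubnetworkStats | None = None) -> ModuleStats:
    """Tally internal weights and member degree sums for every module.

    Degree sums are accumulated edge-wise, adding 2w in one step when an
    edge lies inside a module; together with identical accumulation
    order for internal and total weights this makes the all-in-one
    partition score exactly zero (each bracket is exactly 1 - 1).
    """
    partition.require_covers(net)
    st = ModuleStats(n_modules=partition.n_modules)
    for u, v, w, ch in net.edges():
        cu, cv = partition[u], partition[v]
        same = cu == cv
        if ch == "AA":
            if same:
                st.lA[cu] = st.lA.get(cu, 0.0) + w
                st.dA[cu] = st.dA.get(cu, 0.0) + 2 * w
            else:
                st.dA[cu] = st.dA.get(cu, 0.0) + w
                st.dA[cv] = st.dA.get(cv, 0.0) + w
        elif ch == "BB":
            if same:
                st.lB[cu] = st.lB.get(cu, 0.0) + w
                st.dB[cu] = st.dB.get(cu, 0.0) + 2 * w
            else:
                st.dB[cu] = st.dB.get(cu, 0.0) + w
                st.dB[cv] = st.dB.get(cv, 0.0) + w
        else:
            if same:
                st.lPi[cu] = st.lPi.get(cu, 0.0) + w
            ca, cb = (cu, cv) if net.node_class(u) == NodeClass.A else (cv, cu)
            st.kPi[ca] = st.kPi.get(ca, 0.0) + w
            st.dPi[cb] = st.dPi.get(cb, 0.0) + w
    return st


def mixed_modularity(
    net: HetNet,
    partition: Partition,
    subnet: SubnetworkStats | None = None,
    cached: ModuleStats | None = None,
) -> float:
    """Mixed modularity mQ of a partition of a 2-HN.

    Precomputed :func:`subnetwork_stats` / :func:`module_stats` results
    may be passed to avoid recomputation; they must be consistent with
    ``net`` and ``partition``.
    """
    if len(partition) == 0:
        raise HetNetError("empty partition")
    partition.require_covers(net)
    if subnet is None:
        subnet = subnetwork_stats(net)
    if cached is None:
        cached = module_stats(net, partition, subnet)
    mA, mPi, mB = subnet.mA, subnet.mPi, subnet.mB
    if mA == 0 and mPi == 0 and mB == 0:
        raise HetNetError("mixed modularity undefined: all channels empty")
    q = 0.0
    for c in set(partition.assignment.values()):
        if mA > 0:
            q += cached.lA.get(c, 0.0) / mA - (cached.dA.get(c, 0.0) / (2 * mA)) ** 2
        if mPi > 0:
            q += cached.lPi.get(c, 0.0) / mPi - cached.kPi.get(c, 0.0) * cached.dPi.get(c, 0.0) / mPi**2
        if mB > 0:
            q += cached.lB.get(c, 0.0) / mB - (cached.dB.get(c, 0.0) / (2 * mB)) ** 2
    return q / 3.0


def move_gain(
    net: HetNet,
    partition: Partition,
    node: str,
    target_module: int,
    cached: ModuleStats | None = None,
    subnet: SubnetworkStats | None = None,
) -> float:
    """Change in mQ from moving one node to ``target_module``.

    Computed incrementally from the node's incident edges and the cached
    per-module sums, in O(degree(node)).  ``target_module`` may be a
    fresh (empty) module id.  Moving a node to its own module gives 0.
    """
    if subnet is None:
        subnet = subnetwork_stats(net)
    if cached is None:
        cached = module_stats(net, partition, subnet)
    c = partition[node]
    d = target_module
    if c == d:
        return 0.0
    cls = net.node_class(node)
    mA, mPi, mB = subnet.mA, subnet.mPi, subnet.mB

    # weight from `node` to modules c and d, per channel (self-loops excluded:
    # they travel with the node and cancel in the difference)
    w_same_c = w_same_d = w_pi_c = w_pi_d = 0.0
    for u, v, w, ch in net.edges():
        if u == v:
            continue
        if u == node:
            other = v
        elif v == node:
            other = u
        else:
            continue
        m = partition[other]
        if ch == "AB":
            if m == c:
                w_pi_c += w
            if m == d:
                w_pi_d += w
        else:
            if m == c:
                w_same_c += w
            if m == d:
                w_same_d += w

    gain = 0.0
    if cls == NodeClass.A:
        dAi = subnet.dA.get(node, 0.0)
        kPii = subnet.kPi.get(node, 0.0)
        if mA > 0:
            DAc = cached.dA.get(c, 0.0) - dAi  # module sums with the node removed
            DAd = cached.dA.get(d, 0.0)
            gain += (w_same_d - w_same_c) / mA + dAi * (DAc - DAd) / (2 * mA**2)
        if mPi > 0:
            DPic = cached.dPi.get(c, 0.0)
            DPid = cached.dPi.get(d, 0.0)
            gain += (w_pi_d - w_pi_c) / mPi + kPii * (DPic - DPid) / mPi**2
    else:
        dBi = subnet.dB.get(node, 0.0)
        dPii = subnet.dPi.get(node, 0.0)
        if mB > 0:
            DBc = cached.dB.get(c, 0.0) - dBi
            DBd = cached.dB.get(d, 0.0)
            gain += (w_same_d - w_same_c) / mB + dBi * (DBc - DBd) / (2 * mB**2)
        if mPi > 0:
            KPic = cached.kPi.get(c, 0.0)
            KPid = cached.kPi.get(d, 0.0)
            gain += (w_pi_d - w_pi_c) / mPi + dPii * (KPic - KPid) / mPi**2
    return gain / 3.0
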