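"""2-class heterogeneous network (2-HN) data model and TSV I/O.

A 2-HN carries two node classes (A and B -- in the chemical-gene
applications A is the chemical/drug side and B the gene side) and three
undirected, weighted edge channels: A-A (e.g. structural similarity),
A-B (chemical-target interaction) and B-B (gene-gene interaction).  The
channel of an edge is fully determined by the classes of its endpoints,
so it is derived, never stored independently.

Input networks are simple graphs (no self-loops, no parallel edges).
Self-loops appear only in the coarse graphs built internally during
Louvain aggregation; there a self-loop of weight ``w`` contributes ``w``
to its channel's total weight and ``2w`` to its node's degree.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping


class NodeClass(str, Enum):
    """The two node classes of a 2-HN."""

    A = "A"
    B = "B"


#: Edge channels, derived from endpoint classes.
CHANNELS = ("AA", "AB", "BB")


class HetNetError(ValueError):
    """Raised for invalid 2-HN input (unknown nodes, bad weights, ...)."""


def channel_of(cu: NodeClass, cv: NodeClass) -> str:
    """Channel implied by the endpoint classes (AA, AB or BB)."""
    if cu == NodeClass.A and cv == NodeClass.A:
        return "AA"
    if cu == NodeClass.B and cv == NodeClass.B:
        return "BB"
    return "AB"


def _canon(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


class HetNet:
    """An undirected, weighted 2-class heterogeneous network.

    Parameters
    ----------
    nodes:
        Mapping node id -> :class:`NodeClass` (``"A"``/``"B"`` accepted).
    edges:
        Iterable of ``(u, v, weight)`` triples.  Unweighted networks use
        weight 1.  Duplicate rows for one unordered pair are rejected.
    allow_self_loops:
        Permit ``u == v`` edges.  Off for input networks; used internally
        by the Louvain aggregation step.
    """

    def __init__(
        self,
        nodes: Mapping[str, NodeClass | str],
        edges: Iterable[tuple[str, str, float]] = (),
        *,
        allow_self_loops: bool = False,
    ) -> None:
        self._nodes: dict[str, NodeClass] = {}
        for nid, cls in nodes.items():
            try:
                self._nodes[str(nid)] = NodeClass(cls)
            except ValueError:
                raise HetNetError(f"node {nid!r}: class must be A or B, got {cls!r}")
        self._edges: dict[tuple[str, str], float] = {}
        self.allow_self_loops = allow_self_loops
        for u, v, w in edges:
            self.add_edge(u, v, w)

    # -- construction -------------------------------------------------

    def add_edge(self, u: str, v: str, weight: float = 1.0) -> None:
        if u not in self._nodes:
            raise HetNetError(f"edge ({u!r}, {v!r}): unknown node {u!r}")
        if v not in self._nodes:
            raise HetNetError(f"edge ({u!r}, {v!r}): unknown node {v!r}")
        if u == v and not self.allow_self_loops:
            raise HetNetError(f"self-loop on {u!r} not allowed in input networks")
        w = float(weight)
        if not w > 0:
            raise HetNetError(f"edge ({u!r}, {v!r}): weight must be > 0, got {weight}")
        key = _canon(u, v)
        if key in self._edges:
            raise HetNetError(f"duplicate edge for pair ({u!r}, {v!r})")
        self._edges[key] = w

    # -- basic queries ------------------------------------------------

    @property
    def nodes(self) -> dict[str, NodeClass]:
        return dict(self._nodes)

    def node_class(self, nid: str) -> NodeClass:
        return self._nodes[nid]

    def nodes_of_class(self, cls: NodeClass | str) -> list[str]:
        cls = NodeClass(cls)
        return [n for n, c in self._nodes.items() if c == cls]

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def edges(self) -> Iterator[tuple[str, str, float, str]]:
        """Yield ``(u, v, weight, channel)`` for every edge."""
        for (u, v), w in self._edges.items():
            yield u, v, w, channel_of(self._nodes[u], self._nodes[v])

    def edge_weight(self, u: str, v: str) -> float | None:
        return self._edges.get(_canon(u, v))

    def edge_channel(self, u: str, v: str) -> str:
        return channel_of(self._nodes[u], self._nodes[v])

    def __contains__(self, nid: str) -> bool:
        return nid in self._nodes

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HetNet):
            return NotImplemented
        return self._nodes == other._nodes and self._edges == other._edges

    def __repr__(self) -> str:
        na = len(self.nodes_of_class("A"))
        nb = len(self.nodes_of_class("B"))
        return f"HetNet({na} A + {nb} B nodes, {self.n_edges} edges)"

    def scale_channel(self, channel: str, factor: float) -> "HetNet":
        """Return a copy with all weights of one channel multiplied by ``factor``."""
        if channel not in CHANNELS:
            raise HetNetError(f"unknown channel {channel!r}")
        if not factor > 0:
            raise HetNetError("scale factor must be positive")
        out = HetNet(self._nodes, allow_self_loops=self.allow_self_loops)
        for u, v, w, ch in self.edges():
            out.add_edge(u, v, w * factor if ch == channel else w)
        return out


@dataclass
class SubnetworkStats:
    """Per-channel totals and node degrees of the three subnetworks.

    ``mA``/``mPi``/``mB`` are the total weights of the AA, AB and BB
    channels (a self-loop counts once).  ``dA``/``dB`` map nodes to their
    weighted degree inside G_A / G_B (a self-loop counts twice), ``kPi``
    maps A nodes and ``dPi`` maps B nodes to their weighted degree in the
    bipartite subnetwork G_Pi.  Degrees in channels a node cannot touch
    are simply absent (treated as zero).
    """

    mA: float = 0.0
    mPi: float = 0.0
    mB: float = 0.0
    dA: dict[str, float] = field(default_factory=dict)
    kPi: dict[str, float] = field(default_factory=dict)
    dPi: dict[str, float] = field(default_factory=dict)
    dB: dict[str, float] = field(default_factory=dict)


def subnetwork_stats(net: HetNet) -> SubnetworkStats:
    """Decompose a 2-HN into its three channels and tally weights/degrees.

    Degrees are computed strictly per channel -- an AA edge never enters
    a node's bipartite or BB degree.
    """
    st = SubnetworkStats()
    for u, v, w, ch in net.edges():
        loop = u == v
        if ch == "AA":
            st.mA += w
            st.dA[u] = st.dA.get(u, 0.0) + (2 * w if loop else w)
            if not loop:
                st.dA[v] = st.dA.get(v, 0.0) + w
        elif ch == "BB":
            st.mB += w
            st.dB[u] = st.dB.get(u, 0.0) + (2 * w if loop else w)
            if not loop:
                st.dB[v] = st.dB.get(v, 0.0) + w
        else:
            st.mPi += w
            a, b = (u, v) if net.node_class(u) == NodeClass.A else (v, u)
            st.kPi[a] = st.kPi.get(a, 0.0) + w
            st.dPi[b] = st.dPi.get(b, 0.0) + w
    return st


class Partition:
    """Assignment of every node of a network to a module.

    Module ids are canonicalized to contiguous non-negative integers in
    order of first appearance over sorted node ids, so two partitions
    with the same blocks compare equal regardless of input labels.
    """

    def __init__(self, assignment: Mapping[str, object], *, canonicalize: bool = True):
        if canonicalize:
            remap: dict[object, int] = {}
            self.assignment: dict[str, int] = {}
            for nid in sorted(assignment):
                lab = assignment[nid]
                if lab not in remap:
                    remap[lab] = len(remap)
                self.assignment[nid] = remap[lab]
        else:
            self.assignment = {n: int(m) for n, m in assignment.items()}

    @classmethod
    def singletons(cls, net: HetNet) -> "Partition":
        return cls({n: i for i, n in enumerate(sorted(net.nodes))}, canonicalize=False)

    @property
    def modules(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for n, m in self.assignment.items():
            out.setdefault(m, set()).add(n)
        return out

    @property
    def n_modules(self) -> int:
        return len(set(self.assignment.values()))

    def __getitem__(self, nid: str) -> int:
        return self.assignment[nid]

    def __len__(self) -> int:
        return len(self.assignment)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        return Partition(self.assignment).assignment == Partition(other.assignment).assignment

    def covers(self, net: HetNet) -> bool:
        return set(self.assignment) == set(net.nodes)

    def require_covers(self, net: HetNet) -> None:
        if not self.covers(net):
            raise HetNetError("partition does not cover the network's node set")


# ---------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------

def read_hetnet(
    node_table_path: str | Path,
    edge_table_path: str | Path,
) -> tuple[HetNet, dict[str, int] | None]:
    """Read a 2-HN from a node TSV and an edge TSV.

    Node table columns: ``node_id``, ``class`` and optionally ``module``
    (integer ground-truth label).  Edge table columns: ``u``, ``v`` and
    optionally ``weight`` (default 1).  Returns ``(net, labels)`` where
    ``labels`` is the ground-truth map if the module column is present,
    else ``None``.
    """
    nodes: dict[str, str] = {}
    labels: dict[str, int] = {}
    have_labels = False
    with open(node_table_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "node_id" not in reader.fieldnames or "class" not in reader.fieldnames:
            raise HetNetError("node table must have node_id and class columns")
        have_labels = "module" in reader.fieldnames
        for row in reader:
            nid = row["node_id"]
            if nid in nodes:
                raise HetNetError(f"duplicate node row {nid!r}")
            nodes[nid] = row["class"]
            if have_labels:
                labels[nid] = int(row["module"])
    net = HetNet(nodes)
    with open(edge_table_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "u" not in reader.fieldnames or "v" not in reader.fieldnames:
            raise HetNetError("edge table must have u and v columns")
        have_w = "weight" in reader.fieldnames
        for row in reader:
            w = float(row["weight"]) if have_w and row["weight"] != "" else 1.0
            net.add_edge(row["u"], row["v"], w)
    return net, (labels if have_labels else None)


def write_hetnet(
    net: HetNet,
    node_table_path: str | Path,
    edge_table_path: str | Path,
    labels: Mapping[str, int] | None = None,
) -> None:
    """Write a 2-HN as node/edge TSVs (round-trips through :func:`read_hetnet`)."""
    with open(node_table_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        if labels is not None:
            w.writerow(["node_id", "class", "module"])
            for nid in sorted(net.nodes):
                w.writerow([nid, net.node_class(nid).value, labels[nid]])
        else:
            w.writerow(["node_id", "class"])
            for nid in sorted(net.nodes):
                w.writerow([nid, net.node_class(nid).value])
    with open(edge_table_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["u", "v", "weight"])
        for u, v, wt, _ in sorted(net.edges()):
            w.writerow([u, v, repr(wt)])


def read_partition(path: str | Path) -> Partition:
    """Read a node->module TSV (columns ``node_id``, ``module_id``)."""
    assignment: dict[str, int] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            assignment[row["node_id"]] = int(row["module_id"])
    return Partition(assignment)


def write_partition(partition: Partition, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["node_id", "module_id"])
        for nid in sorted(partition.assignment):
            w.writerow([nid, partition.assignment[nid]])


def export_module_network(
    net: HetNet,
    partition: Partition,
    out_path: str | Path,
    supernode_path: str | Path | None = None,
) -> None:
    """Export the coarse module network induced by a partition.

    Each module contributes up to two supernodes -- its A-side and its
    B-side submodule.  A supernode's self-loop weight is the internal
    weight of that submodule; coarse edges carry the aggregated weight
    between submodules and are flagged intra (same module) or inter.
    Written as an edge TSV ``src dst weight intra``; if
    ``supernode_path`` is given, a supernode table
    ``supernode_id module_id class size self_loop_weight`` accompanies it.
    """
    partition.require_covers(net)
    sizes: dict[tuple[int, str], int] = {}
    for nid, cls in net.nodes.items():
        key = (partition[nid], cls.value)
        sizes[key] = sizes.get(key, 0) + 1
    self_loops: dict[tuple[int, str], float] = {}
    coarse: dict[tuple[tuple[int, str], tuple[int, str]], float] = {}
    for u, v, w, _ in net.edges():
        ku = (partition[u], net.node_class(u).value)
        kv = (partition[v], net.node_class(v).value)
        if ku == kv:
            self_loops[ku] = self_loops.get(ku, 0.0) + w
        else:
            key = (min(ku, kv), max(ku, kv))
            coarse[key] = coarse.get(key, 0.0) + w

    def name(key: tuple[int, str]) -> str:
        return f"M{key[0]}{key[1]}"

    with open(out_path, "w", newline="") as fh:
        wr = csv.writer(fh, delimiter="\t", lineterminator="\n")
        wr.writerow(["src", "dst", "weight", "intra"])
        for key in sorted(self_loops):
            wr.writerow([name(key), name(key), repr(self_loops[key]), 1])
        for (ku, kv) in sorted(coarse):
            intra = 1 if ku[0] == kv[0] else 0
            wr.writerow([name(ku), name(kv), repr(coarse[(ku, kv)]), intra])
    if supernode_path is not None:
        with open(supernode_path, "w", newline="") as fh:
            wr = csv.writer(fh, delimiter="\t", lineterminator="\n")
            wr.writerow(["supernode_id", "module_id", "class", "size", "self_loop_weight"])
            for key in sorted(sizes):
                wr.writerow([name(key), key[0], key[1], sizes[key], repr(self_loops.get(key, 0.0))])
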