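"""Construction of real chemical-gene 2-HNs and their statistical checks.

The drug-target and herbal-formula applications build their three
channels from different sources: the A-A channel links chemicals whose
fingerprint Tanimoto similarity reaches a threshold (0.7 by default),
the A-B channel holds curated chemical-gene interactions, and the B-B
channel holds gene-gene interactions weighted by the number of source
databases reporting them.  Two statistical checks accompany the
construction: a Spearman correlation between chemical similarity and
the interaction density of the chemicals' target sets, and a label
permutation test for whether curated clusters align with the network's
module structure.
"""

from __future__ import annotations

import random
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .hetnet import HetNet, HetNetError, NodeClass, Partition
from .modularity import mixed_modularity

Fingerprint = frozenset  # set of on-bit indices


def as_fingerprint(bits: Iterable[int] | str) -> Fingerprint:
    """Build a fingerprint from on-bit indices or a '0101...' bit string."""
    if isinstance(bits, str):
        return frozenset(i for i, b in enumerate(bits) if b == "1")
    return frozenset(int(b) for b in bits)


def tanimoto(f1: Fingerprint, f2: Fingerprint) -> float:
    """Tanimoto coefficient |f1 & f2| / |f1 | f2| of two bit sets."""
    union = len(f1 | f2)
    if union == 0:
        raise HetNetError("Tanimoto undefined for two all-zero fingerprints")
    return len(f1 & f2) / union


def similarity_edges(
    fingerprints: Mapping[str, Fingerprint],
    threshold: float = 0.7,
    weighted: bool = False,
) -> list[tuple[str, str, float]]:
    """All chemical pairs with Tanimoto similarity >= threshold (inclusive).

    Edges carry weight 1 by default; with ``weighted=True`` the
    similarity value itself becomes the weight.
    """
    if not 0 <= threshold <= 1:
        raise HetNetError("threshold must be in [0, 1]")
    ids = sorted(fingerprints)
    out = []
    for i, u in enumerate(ids):
        for v in ids[i + 1:]:
            sim = tanimoto(fingerprints[u], fingerprints[v])
            if sim >= threshold:
                out.append((u, v, sim if weighted else 1.0))
    return out


def gene_edges(
    tables: Sequence[Iterable[tuple[str, str]]],
) -> list[tuple[str, str, float]]:
    """Gene-gene edges weighted by the number of distinct source databases.

    ``tables`` is one iterable of (gene, gene) pairs per database;
    duplicates within a database count once.
    """
    sources: dict[tuple[str, str], set[int]] = {}
    for db_index, table in enumerate(tables):
        for u, v in table:
            if u == v:
                continue
            key = (u, v) if u <= v else (v, u)
            sources.setdefault(key, set()).add(db_index)
    return [(u, v, float(len(dbs))) for (u, v), dbs in sorted(sources.items())]


def build_2hn(
    similarity_edges: Iterable[tuple[str, str, float]],
    chem_gene_edges: Iterable[tuple[str, str]] | Iterable[tuple[str, str, float]],
    gene_edges: Iterable[tuple[str, str, float]],
    extra_chemicals: Iterable[str] = (),
    extra_genes: Iterable[str] = (),
) -> HetNet:
    """Integrate the three channels into a validated 2-HN.

    Node classes are implied by which channel a node appears in;
    ``extra_chemicals`` / ``extra_genes`` declare isolated nodes that
    should be retained.  A node appearing on the chemical side of one
    channel and the gene side of another is a curation error and is
    rejected.
    """
    sim = [(u, v, w) for u, v, w in similarity_edges]
    cg = [e if len(e) == 3 else (e[0], e[1], 1.0) for e in chem_gene_edges]
    gg = [(u, v, w) for u, v, w in gene_edges]
    chems = set(extra_chemicals)
    genes = set(extra_genes)
    for u, v, _ in sim:
        chems.update((u, v))
    for c, g, _ in cg:
        chems.add(c)
        genes.add(g)
    for u, v, _ in gg:
        genes.update((u, v))
    clash = chems & genes
    if clash:
        raise HetNetError(f"nodes appear as both chemical and gene: {sorted(clash)[:5]}")
    nodes = {c: "A" for c in sorted(chems)}
    nodes.update({g: "B" for g in sorted(genes)})
    net = HetNet(nodes)
    for u, v, w in sim + cg + gg:
        net.add_edge(u, v, w)
    return net


def target_sets(net: HetNet) -> dict[str, set[str]]:
    """Map each A node to the set of B nodes it touches in the AB channel."""
    out: dict[str, set[str]] = {a: set() for a in net.nodes_of_class("A")}
    for u, v, _, ch in net.edges():
        if ch != "AB":
            continue
        a, b = (u, v) if net.node_class(u) == NodeClass.A else (v, u)
        out[a].add(b)
    return out


def similarity_interaction_correlation(
    net: HetNet,
    fingerprints: Mapping[str, Fingerprint],
    count_shared_targets: bool = True,
    count_bb_edges: bool = True,
) -> dict[str, float | int]:
    """Spearman correlation of chemical similarity vs target-set interaction.

    For every unordered pair of A nodes, x is the fingerprint Tanimoto
    similarity and y the number of B-B edges running between the two
    target sets, plus (by default) the number of shared targets -- a
    shared target being the tightest possible coupling of two target
    sets.  Returns Spearman rho with its large-sample p-value.
    """
    tsets = target_sets(net)
    bb_adj: dict[str, set[str]] = {}
    for u, v, _, ch in net.edges():
        if ch == "BB":
            bb_adj.setdefault(u, set()).add(v)
            bb_adj.setdefault(v, set()).add(u)
    ids = sorted(a for a in tsets if a in fingerprints)
    xs, ys = [], []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            ta, tb = tsets[a], tsets[b]
            y = 0
            if count_shared_targets:
                y += len(ta & tb)
            if count_bb_edges:
                y += sum(1 for g in ta for h in bb_adj.get(g, ()) if h in tb)
            xs.append(tanimoto(fingerprints[a], fingerprints[b]))
            ys.append(y)
    if len(xs) < 3 or len(set(xs)) == 1 or len(set(ys)) == 1:
        raise HetNetError("correlation undefined: too few pairs or zero variance")
    rho, pval = stats.spearmanr(xs, ys)
    return {"rho": float(rho), "p_value": float(pval), "n_pairs": len(xs)}


def label_permutation_test(
    net: HetNet,
    labels: Mapping[str, int],
    n_perm: int = 999,
    seed: int = 0,
) -> dict[str, float]:
    """Do curated cluster labels beat chance as a module structure?

    The observed statistic is the mixed modularity of the label
    partition.  The null shuffles labels within each node class
    (preserving class sizes and each class's label profile);
    empirical p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    if n_perm < 99:
        raise HetNetError("n_perm must be >= 99 for a meaningful p-value")
    part = Partition(dict(labels))
    part.require_covers(net)
    observed = mixed_modularity(net, part)
    rng = random.Random(seed)
    a_nodes = net.nodes_of_class("A")
    b_nodes = net.nodes_of_class("B")
    null = np.empty(n_perm)
    for i in range(n_perm):
        shuffled: dict[str, int] = {}
        for group in (a_nodes, b_nodes):
            labs = [labels[n] for n in group]
            rng.shuffle(labs)
            shuffled.update(zip(group, labs))
        null[i] = mixed_modularity(net, Partition(shuffled))
    exceed = int((null >= observed).sum())
    return {
        "observed_mQ": observed,
        "null_mean": float(null.mean()),
        "null_sd": float(null.std(ddof=1)) if n_perm > 1 else 0.0,
        "null_max": float(null.max()),
        "empirical_p": (1 + exceed) / (n_perm + 1),
    }
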