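"""Partition-comparison metrics: NMI and classification accuracy.

Both metrics compare a "real" (planted or curated) partition with a
"found" partition over the same node set, through their confusion
matrix ``N_ij`` = number of nodes in real module i and found module j.

NMI is the Danon confusion-matrix form with natural logarithms,

    NMI = -2 sum_ij N_ij ln(N_ij N / (N_i. N_.j))
          / [sum_i N_i. ln(N_i./N) + sum_j N_.j ln(N_.j/N)],

1 for identical partitions, 0 for independent ones.  Classification
accuracy (CA) finds the one-to-one matching between real and found
modules that maximizes total overlap and reports the matched fraction
of nodes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Mapping

import numpy as np
from scipy.optimize import linear_sum_assignment

from .hetnet import HetNet, HetNetError, Partition
from .detect import classify_modules


PartitionLike = Partition | Mapping[str, int]


def _assignment(p: PartitionLike) -> dict[str, int]:
    if isinstance(p, Partition):
        return p.assignment
    return dict(p)


@dataclass
class ConfusionMatrix:
    """Counts ``N_ij`` of nodes shared by real module i and found module j."""

    counts: np.ndarray
    real_ids: list[int]
    found_ids: list[int]

    @classmethod
    def from_partitions(cls, real: PartitionLike, found: PartitionLike) -> "ConfusionMatrix":
        ra, fa = _assignment(real), _assignment(found)
        if set(ra) != set(fa):
            raise HetNetError("partitions cover different node sets")
        real_ids = sorted(set(ra.values()))
        found_ids = sorted(set(fa.values()))
        ri = {m: i for i, m in enumerate(real_ids)}
        fi = {m: j for j, m in enumerate(found_ids)}
        counts = np.zeros((len(real_ids), len(found_ids)), dtype=np.int64)
        for n, rm in ra.items():
            counts[ri[rm], fi[fa[n]]] += 1
        return cls(counts=counts, real_ids=real_ids, found_ids=found_ids)

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def nmi(real: PartitionLike, found: PartitionLike) -> float:
    """Normalized mutual information between two partitions, in [0, 1]."""
    ra, fa = _assignment(real), _assignment(found)
    if Partition(ra) == Partition(fa):
        return 1.0  # identical block structure, exactly
    cm = ConfusionMatrix.from_partitions(real, found)
    N = cm.n
    counts = cm.counts
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    num = 0.0
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            nij = counts[i, j]
            if nij > 0:
                num += nij * math.log(nij * N / (row[i] * col[j]))
    num *= -2.0
    den = sum(r * math.log(r / N) for r in row if r > 0) + sum(
        c * math.log(c / N) for c in col if c > 0
    )
    if den == 0.0:
        # both partitions trivial (each one single module): identical
        return 1.0
    val = num / den
    # clip the odd 1e-16 excursion from floating accumulation
    return min(1.0, max(0.0, val))


def classification_accuracy(
    real: PartitionLike, found: PartitionLike, matching: str = "optimal"
) -> float:
    """Fraction of nodes in the overlaps of the best module matching.

    ``matching="optimal"`` solves the maximum-weight one-to-one
    assignment on the confusion matrix; ``"greedy"`` repeatedly takes
    the largest remaining overlap.
    """
    cm = ConfusionMatrix.from_partitions(real, found)
    counts = cm.counts
    if matching == "optimal":
        ri, fj = linear_sum_assignment(counts, maximize=True)
        overlap = int(counts[ri, fj].sum())
    elif matching == "greedy":
        c = counts.astype(float).copy()
        overlap = 0
        for _ in range(min(c.shape)):
            i, j = np.unravel_index(np.argmax(c), c.shape)
            if c[i, j] <= 0:
                break
            overlap += int(c[i, j])
            c[i, :] = -1
            c[:, j] = -1
    else:
        raise ValueError("matching must be 'optimal' or 'greedy'")
    return overlap / cm.n


def brute_force_ca(real: PartitionLike, found: PartitionLike) -> float:
    """CA by exhaustive search over all permutation matchings.

    Exponential; the independent check for small instances only.
    """
    cm = ConfusionMatrix.from_partitions(real, found)
    counts = cm.counts
    nr, nf = counts.shape
    best = 0
    if nr <= nf:
        for perm in permutations(range(nf), nr):
            best = max(best, sum(counts[i, perm[i]] for i in range(nr)))
    else:
        for perm in permutations(range(nr), nf):
            best = max(best, sum(counts[perm[j], j] for j in range(nf)))
    return best / cm.n


def resolve_multilabels(
    multilabels: Mapping[str, set[int] | frozenset[int] | int],
    found: PartitionLike,
) -> dict[str, int]:
    """Collapse multi-label ground truth to one label per node.

    Some curated networks give a minority of nodes several true module
    labels.  Each such node is resolved to the candidate label most
    represented (by single-label nodes) in the node's found module, so
    the downstream metrics operate on an ordinary partition; ties and
    unrepresented candidates fall back to the smallest candidate label.
    """
    fa = _assignment(found)
    single: dict[str, int] = {}
    multi: dict[str, frozenset[int]] = {}
    for n, lab in multilabels.items():
        if isinstance(lab, (set, frozenset)):
            if len(lab) == 1:
                single[n] = next(iter(lab))
            else:
                multi[n] = frozenset(lab)
        else:
            single[n] = int(lab)
    votes: dict[tuple[int, int], int] = {}
    for n, lab in single.items():
        key = (fa[n], lab)
        votes[key] = votes.get(key, 0) + 1
    out = dict(single)
    for n, cands in multi.items():
        fm = fa[n]
        out[n] = max(sorted(cands), key=lambda lab: votes.get((fm, lab), 0))
    return out


def evaluate(
    real: PartitionLike,
    found: PartitionLike,
    net: HetNet | None = None,
    matching: str = "optimal",
) -> dict[str, float | int]:
    """Bundle NMI, CA and module counts into one report row."""
    found_a = _assignment(found)
    row: dict[str, float | int] = {
        "n_modules_found": len(set(found_a.values())),
        "nmi": nmi(real, found),
        "ca": classification_accuracy(real, found, matching=matching),
    }
    if net is not None:
        kinds = classify_modules(net, found if isinstance(found, Partition) else Partition(found_a))
        row["n_mixed_found"] = sum(1 for k in kinds.values() if k == "mixed")
    return row
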