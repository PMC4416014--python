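"""Parameter-sweep harness: generate -> detect -> evaluate over a grid.

Mirrors the benchmark experimental design: every grid cell (a
combination of muA, muB and p) is evaluated on several independently
generated 2-HNs, and cell means are reported alongside the per-run
rows.  Replicate seeds are derived as ``base_seed + replicate_index``
so any single run can be reproduced in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import pandas as pd

from .benchgen import BenchmarkSpec, GenerationError, generate_benchmark
from .detect import DetectConfig, mixmod_detect
from .metrics import evaluate


@dataclass
class SweepSpec:
    """Grid over (muA, muB, p) with a common base benchmark spec."""

    muA_values: Sequence[float] = (0.2,)
    muB_values: Sequence[float] = (0.2,)
    p_values: Sequence[float] = (0.5,)
    replicates: int = 10
    base: BenchmarkSpec = field(default_factory=BenchmarkSpec)
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not (self.muA_values and self.muB_values and self.p_values):
            raise ValueError("grid must be non-empty")


def run_sweep(spec: SweepSpec, progress: bool = False) -> pd.DataFrame:
    """One row per (cell, replicate): generate a benchmark, run MixMod,
    score against the planted labels.  Generation failures are recorded
    in the ``error`` column and skipped."""
    rows = []
    for muA in spec.muA_values:
        for muB in spec.muB_values:
            for p in spec.p_values:
                for rep in range(spec.replicates):
                    seed = spec.base_seed + rep
                    row: dict = {
                        "muA": muA, "muB": muB, "p": p,
                        "replicate": rep, "seed": seed,
                    }
                    try:
                        bench = generate_benchmark(
                            replace(spec.base, muA=muA, muB=muB, p=p, seed=seed)
                        )
                        res = mixmod_detect(bench.net, DetectConfig(seed=seed))
                        ev = evaluate(bench.labels, res.partition, net=bench.net)
                        row.update(
                            nmi=ev["nmi"], ca=ev["ca"],
                            n_modules=res.n_modules, n_mixed=res.n_mixed_modules,
                            mQ=res.mQ, error="",
                        )
                    except GenerationError as err:
                        row.update(
                            nmi=float("nan"), ca=float("nan"),
                            n_modules=0, n_mixed=0, mQ=float("nan"),
                            error=str(err),
                        )
                    rows.append(row)
                    if progress:
                        print(
                            f"muA={muA} muB={muB} p={p} rep={rep}: "
                            f"nmi={row['nmi']:.4f} ca={row['ca']:.4f}"
                        )
    return pd.DataFrame(rows)


def summarize_sweep(table: pd.DataFrame) -> pd.DataFrame:
    """Cell means and standard deviations of NMI and CA."""
    g = table.groupby(["muA", "muB", "p"], as_index=False)
    out = g.agg(
        n_runs=("nmi", "count"),
        mean_nmi=("nmi", "mean"),
        sd_nmi=("nmi", "std"),
        mean_ca=("ca", "mean"),
        sd_ca=("ca", "std"),
        mean_modules=("n_modules", "mean"),
        mean_mixed=("n_mixed", "mean"),
    )
    return out
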