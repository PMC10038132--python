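"""In-memory simulation benchmark: simulate a grid, trim it, score it.

Mirrors the benchmark protocol of the accuracy comparison: only adapter
trimming runs (consensus and quality trimming disabled — neither changes
read lengths on constant-quality simulated data, so the accuracy metrics
are protocol-independent), the trimmer is configured with the full-length
adapter pair, and every condition of the grid is fully crossed.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .metrics import TrimMetrics, evaluate_lengths
from .pipeline import RunConfig, process_pair
from .simulate import iter_grid

__all__ = ["benchmark_config", "run_benchmark"]


def benchmark_config(**overrides) -> RunConfig:
    """Trimmer defaults for accuracy benchmarks: adapter trimming only."""
    params = dict(consensus=False, quality_trim=False)
    params.update(overrides)
    return RunConfig(**params)


def run_benchmark(
    profiles: Sequence[float] = (1.0,),
    adapter_lengths: Sequence[int] = (16, 20, 24, 28, 33),
    insert_sizes: Sequence[int] = tuple(range(66, 99, 2)),
    pairs_per_condition: int = 500,
    read_length: int = 100,
    seed: int = 1,
    cfg: RunConfig | None = None,
) -> TrimMetrics:
    """Simulate the grid, run the trimmer on every pair and evaluate.

    Everything stays in memory; the truth table and trimmed lengths are
    aligned by construction.
    """
    if cfg is None:
        cfg = benchmark_config()
    adapters = cfg.packed_adapters()
    trimmed_lengths: list[int] = []
    true_positions: list[int] = []
    read_lengths: list[int] = []
    for r1, r2, truth, _row in iter_grid(
        profiles=profiles,
        adapter_lengths=adapter_lengths,
        insert_sizes=insert_sizes,
        pairs_per_condition=pairs_per_condition,
        read_length=read_length,
        adapter1=cfg.adapter1,
        adapter2=cfg.adapter2,
        seed=seed,
    ):
        kept, _info = process_pair(r1, r2, cfg, adapters)
        assert kept is not None  # benchmark config never drops pairs
        trimmed_lengths.extend((len(kept[0].bases), len(kept[1].bases)))
        true_positions.extend((truth.true_trim_pos_r1, truth.true_trim_pos_r2))
        read_lengths.extend((read_length, read_length))
    return evaluate_lengths(
        np.array(trimmed_lengths), np.array(true_positions), np.array(read_lengths)
    )
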