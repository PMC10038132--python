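"""Run configuration and the per-pair trimming pipeline.

Stage order: adapter trim -> consensus -> quality trim -> N-trim ->
hard clip -> length filter.  ``threads`` is accepted for interface
compatibility but the implementation is single-threaded; results are
identical at any thread count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Iterator

from .consensus import DEFAULT_MAX_MISMATCH_RATIO, consensus_call
from .decision import DEFAULT_TAIL_LENGTH, DEFAULT_TRIM_SCORE, cut_pair, decide
from .engine import DEFAULT_CUTOFF, DEFAULT_K, four_way_match
from .fastqio import FastqRead, read_pairs, write_pairs
from .filters import (
    DEFAULT_QUALITY_THRESHOLD,
    DEFAULT_WINDOW,
    hard_clip,
    length_filter,
    n_trim,
    quality_trim,
)
from .packedseq import PackedSeq

__all__ = ["RunConfig", "process_pair", "run"]

# Illumina TruSeq-style adapter pair used throughout the benchmarks
DEFAULT_ADAPTER1 = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"
DEFAULT_ADAPTER2 = "AGATCGGAAGAGCGTCGTGTAGGGAAAGAGTGT"


@dataclass
class RunConfig:
    """All tunables of a trimming run, with the documented defaults."""

    adapter1: str = DEFAULT_ADAPTER1
    adapter2: str = DEFAULT_ADAPTER2
    k: int = DEFAULT_K
    cutoff: int = DEFAULT_CUTOFF
    trim_score: float = DEFAULT_TRIM_SCORE
    tail_length: int = DEFAULT_TAIL_LENGTH
    tail_filter_prose: bool = False
    max_mismatch_ratio: float = DEFAULT_MAX_MISMATCH_RATIO
    consensus: bool = True
    quality_trim: bool = True
    window: int = DEFAULT_WINDOW
    quality_threshold: float = DEFAULT_QUALITY_THRESHOLD
    enable_n_trim: bool = False
    clip_front: int = 0
    clip_tail: int = 0
    min_length: int = 0
    threads: int = 1  # accepted for compatibility; single-threaded execution

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("k must be >= 0")
        if not 0 <= self.max_mismatch_ratio <= 1:
            raise ValueError("max_mismatch_ratio must be in [0, 1]")
        if self.window < 1:
            raise ValueError("window must be >= 1")

    def packed_adapters(self) -> tuple[PackedSeq, PackedSeq]:
        return PackedSeq(self.adapter1), PackedSeq(self.adapter2)


def process_pair(
    r1: FastqRead,
    r2: FastqRead,
    cfg: RunConfig,
    adapters: tuple[PackedSeq, PackedSeq] | None = None,
) -> tuple[tuple[FastqRead, FastqRead] | None, dict]:
    """Run the full pipeline on one pair.

    Returns ``(pair or None, info)`` where ``None`` means the pair was
    dropped by the length filter; ``info`` flags which stages acted.
    """
    ad1, ad2 = adapters if adapters is not None else cfg.packed_adapters()
    state = four_way_match(r1, r2, ad1, ad2, cfg.k, cfg.cutoff)
    verdict = decide(
        state, r1, r2, cfg.trim_score, cfg.tail_length, cfg.tail_filter_prose
    )
    out1, out2 = cut_pair(r1, r2, verdict)
    corrected = False
    if cfg.consensus:
        out1, out2, corrected = consensus_call(
            out1, out2, verdict, cfg.k, cfg.max_mismatch_ratio
        )
    if cfg.quality_trim:
        out1 = quality_trim(out1, cfg.window, cfg.quality_threshold)
        out2 = quality_trim(out2, cfg.window, cfg.quality_threshold)
    if cfg.enable_n_trim:
        out1 = n_trim(out1)
        out2 = n_trim(out2)
    if cfg.clip_front or cfg.clip_tail:
        out1 = hard_clip(out1, cfg.clip_front, cfg.clip_tail)
        out2 = hard_clip(out2, cfg.clip_front, cfg.clip_tail)
    info = {
        "trimmed": verdict.trim
        and (len(out1.bases) < len(r1.bases) or len(out2.bases) < len(r2.bases)),
        "verdict": verdict,
        "consensus_corrected": corrected,
    }
    kept = length_filter((out1, out2), cfg.min_length)
    return kept, info


def trim_stream(
    pairs: Iterable[tuple[FastqRead, FastqRead]],
    cfg: RunConfig,
    summary: dict | None = None,
) -> Iterator[tuple[FastqRead, FastqRead]]:
    """Trim an in-memory stream of pairs, accumulating summary counts."""
    ad = cfg.packed_adapters()
    for r1, r2 in pairs:
        kept, info = process_pair(r1, r2, cfg, ad)
        if summary is not None:
            summary["pairs_read"] = summary.get("pairs_read", 0) + 1
            if info["trimmed"]:
                summary["pairs_trimmed"] = summary.get("pairs_trimmed", 0) + 1
            if info["consensus_corrected"]:
                summary["pairs_consensus_corrected"] = (
                    summary.get("pairs_consensus_corrected", 0) + 1
                )
        if kept is None:
            if summary is not None:
                summary["pairs_dropped"] = summary.get("pairs_dropped", 0) + 1
            continue
        yield kept


def run(
    cfg: RunConfig,
    in1: str,
    in2: str,
    out1: str,
    out2: str,
    compress: bool = False,
    summary_path: str | None = None,
) -> dict:
    """Trim two FASTQ files into two output files; return the run summary."""
    summary: dict = {
        "pairs_read": 0,
        "pairs_trimmed": 0,
        "pairs_consensus_corrected": 0,
        "pairs_dropped": 0,
    }
    stream = trim_stream(read_pairs(in1, in2), cfg, summary)
    write_pairs(stream, out1, out2, compress=compress)
    summary["pairs_written"] = summary["pairs_read"] - summary["pairs_dropped"]
    if summary_path is not None:
        with open(summary_path, "wt") as fh:
            json.dump(summary, fh, indent=2)
            fh.write("\n")
    return summary
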