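"""Sliding-window quality trimming and auxiliary trims/filters.

The quality trimmer slides a window from the front of the read; at the
first window whose mean Phred score drops below the threshold, the
window's first base and everything after it are removed.  Windows at the
read tail shorter than the window size use the truncated mean.

Stage order in the pipeline is fixed: adapter trim -> consensus ->
quality trim -> N-trim -> hard clip -> length filter.

Homopolymer trimming and read-complexity filtration are not implemented;
their CLI flags are reserved and rejected with a clear message.
"""

from __future__ import annotations

import numpy as np

from .fastqio import FastqRead
from .scoring import phred_array

__all__ = ["quality_trim", "n_trim", "hard_clip", "length_filter"]

DEFAULT_WINDOW = 5
DEFAULT_QUALITY_THRESHOLD = 15.0


def quality_trim(
    read: FastqRead,
    window: int = DEFAULT_WINDOW,
    threshold: float = DEFAULT_QUALITY_THRESHOLD,
) -> FastqRead:
    """Remove the low-quality tail found by a front-to-back sliding window."""
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    length = len(read.bases)
    if length == 0:
        return read
    ph = phred_array(read.quals).astype(np.float64)
    csum = np.concatenate(([0.0], np.cumsum(ph)))
    starts = np.arange(length)
    ends = np.minimum(starts + window, length)
    means = (csum[ends] - csum[starts]) / (ends - starts)
    failing = means < threshold
    if not failing.any():
        return read
    cut = int(np.argmax(failing))
    return FastqRead(read.id, read.bases[:cut], read.quals[:cut])


def n_trim(read: FastqRead) -> FastqRead:
    """Cut the read at the first ambiguous N call."""
    pos = read.bases.upper().find("N")
    if pos < 0:
        return read
    return FastqRead(read.id, read.bases[:pos], read.quals[:pos])


def hard_clip(read: FastqRead, front: int = 0, tail: int = 0) -> FastqRead:
    """Remove fixed base counts from the front and/or tail.

    Clip counts exceeding the read yield an empty read, not an error.
    """
    if front == 0 and tail == 0:
        return read
    stop = max(len(read.bases) - max(tail, 0), 0)
    start = min(max(front, 0), stop)
    return FastqRead(read.id, read.bases[start:stop], read.quals[start:stop])


def length_filter(
    pair: tuple[FastqRead, FastqRead], min_length: int
) -> tuple[FastqRead, FastqRead] | None:
    """Drop the whole pair when either mate is shorter than ``min_length``."""
    r1, r2 = pair
    if len(r1.bases) < min_length or len(r2.bases) < min_length:
        return None
    return pair
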