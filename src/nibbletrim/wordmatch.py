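"""Popcount-based 16-mer matching.

The head 16-mer of a query is slid along every offset of a subject.  Under
the one-hot nibble encoding, two bases match iff their codes share a bit,
so the number of matched bases between two packed 16-mers ``a`` and ``b``
is ``count_ones(a & b)`` and the mismatch count is ``K = 16 - count_ones``.

Even subject offsets are byte-aligned and compared against ``a0`` (query
bases 0..15); odd offsets are handled with ``a_minus`` (query bases 1..16)
against the next byte-aligned subject word, so an odd-offset comparison
covers query bases 1..16 rather than 0..15.  Offset -1 is excluded.
Subject positions past the end read as gaps and count as mismatches, so a
query overhanging the subject tail can still match partially.

Ambiguity codes carry several bits, so popcounts can exceed 16; matched
bases are clamped to 16 (equivalently K is clamped at 0).  Indels are not
handled here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .packedseq import PackedSeq

__all__ = ["MatchResult", "mismatch_count", "scan", "match_at"]


@dataclass(frozen=True)
class MatchResult:
    """Best 16-mer hit of a query head in a subject.

    ``offset`` is the 0-based subject index of the query start (-1 when the
    subject was empty); ``n_match`` is the matched-base count at that
    offset (``16 - K``); ``found`` is true iff ``K <= k``.
    """

    offset: int
    n_match: int
    found: bool


def mismatch_count(a_word: int, b_word: int) -> int:
    """Mismatches between two packed 16-mers: ``16 - popcount(a & b)``, >= 0."""
    return max(0, 16 - (a_word & b_word).bit_count())


def scan(query: PackedSeq, subject: PackedSeq, k: int) -> MatchResult:
    """Slide the query head along every subject offset; report the best hit.

    Among offsets achieving the minimum mismatch count, the smallest offset
    wins.  ``found`` is set iff that minimum is ``<= k``.
    """
    length = subject.n_bases
    if length == 0 or query.n_bases == 0:
        return MatchResult(-1, 0, False)
    a0, a_minus = query.head_pair()
    bw = subject.byte_words
    n_even = (length + 1) // 2  # offsets 0, 2, 4, ...
    n_odd = length // 2         # offsets 1, 3, 5, ...
    n_match = np.empty(length, dtype=np.int64)
    n_match[0::2] = np.bitwise_count(np.uint64(a0) & bw[:n_even])
    if n_odd:
        n_match[1::2] = np.bitwise_count(np.uint64(a_minus) & bw[1 : n_odd + 1])
    np.minimum(n_match, 16, out=n_match)
    best = int(np.argmax(n_match))  # first maximum == smallest offset of min K
    best_nm = int(n_match[best])
    return MatchResult(best, best_nm, 16 - best_nm <= k)


def match_at(query: PackedSeq, subject: PackedSeq, offset: int) -> int:
    """Matched-base count of the query head at a single subject offset.

    No threshold is applied.  Offsets past the padded buffer compare
    against gaps only.  Odd offsets compare query bases 1..16, mirroring
    :func:`scan`.
    """
    if offset < 0:
        raise ValueError(f"offset must be non-negative, got {offset}")
    a0, a_minus = query.head_pair()
    bw = subject.byte_words
    if offset % 2 == 0:
        n = offset // 2
        word = int(bw[n]) if n < bw.size else 0
        return min((a0 & word).bit_count(), 16)
    n = (offset + 1) // 2
    word = int(bw[n]) if n < bw.size else 0
    return min((a_minus & word).bit_count(), 16)
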