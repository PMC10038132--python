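"""Reconciling the four matches into one trim/no-trim verdict per pair.

Reconciliation is pairwise: within each read the adapter and paired-end
candidates merge (equal positions sum their scores, otherwise the higher
score wins), then the two reads' results merge the same way into
``(r12_pos, r12_score)``.

Safeguards applied before cutting:

* low-quality override — when the reads disagree but one read's score
  clears the trim threshold and its mate either has no base at that
  position or its *unfloored* mean 16-mer accuracy there is below 0.6
  (Phred Q < 5), both reads are trimmed at the confident read's position,
  bypassing the tail filter;
* tail false-positive filter — adapter hits in the last ``tail_length``
  bases are suspect; a pair is left untrimmed when in some read both the
  adapter and paired-end hits sit in the tail (E) while in neither read do
  the two hits agree on a position (not R);
* adjacent-1-bp re-positioning — indels shift the apparent insert size by
  one base, so before cutting, the adapter's first four bases are compared
  at positions s-1, s, s+1 and the best-matching position wins (ties
  prefer s, then the smaller position).  Skipped when s exceeds
  read length - 3, where too little adapter remains to check.

A prose variant of the tail filter (adapter in tail without a paired-end
hit there) is available via ``tail_filter_prose`` for experimentation; the
default follows the stricter both-hits-in-tail definition.
"""

from __future__ import annotations

from dataclasses import dataclass

from .engine import PairMatchState
from .fastqio import FastqRead
from .packedseq import PackedSeq
from .scoring import mean_16mer_prob

__all__ = ["TrimVerdict", "reconcile", "adjust_position", "decide", "cut_pair"]

DEFAULT_TRIM_SCORE = 10.0
DEFAULT_TAIL_LENGTH = 12
LOW_QUALITY_PROB = 0.6


@dataclass(frozen=True)
class TrimVerdict:
    """Per-pair decision: whether and where to cut each read."""

    trim: bool
    insert_size_r1: int
    insert_size_r2: int
    combined_score: float
    reason: str  # agreed | score-max | low-quality-override | rejected-tail-FP | below-threshold


def reconcile(
    a: tuple[int | None, float], b: tuple[int | None, float]
) -> tuple[int | None, float]:
    """Merge two (position, score) candidates.

    Equal positions sum their scores; otherwise the higher score wins
    (ties keep the first argument).  Absent candidates (position ``None``)
    are identity elements.
    """
    pos_a, score_a = a
    pos_b, score_b = b
    if pos_a is None and pos_b is None:
        return None, 0.0
    if pos_a is None:
        return pos_b, score_b
    if pos_b is None:
        return pos_a, score_a
    if pos_a == pos_b:
        return pos_a, score_a + score_b
    return (pos_a, score_a) if score_a >= score_b else (pos_b, score_b)


def adjust_position(read: PackedSeq | FastqRead, adapter: PackedSeq, s: int) -> int:
    """Re-position the cut by matching the adapter's first 4 bases.

    Candidates s, s-1, s+1 are compared (negative candidates skipped;
    out-of-range read bases count as mismatches); the candidate with the
    most matched bases wins, ties preferring s, then the smaller position.
    """
    packed = read if isinstance(read, PackedSeq) else PackedSeq(read.bases)
    ad = adapter.codes[:4]
    codes = packed.codes
    length = packed.n_bases

    def count(cand: int) -> int:
        total = 0
        for j in range(ad.size):
            p = cand + j
            if p < length and (ad[j] & codes[p]):
                total += 1
        return total

    best_pos, best_count = s, count(s)
    for cand in (s - 1, s + 1):
        if cand < 0:
            continue
        c = count(cand)
        if c > best_count:
            best_pos, best_count = cand, c
    return best_pos


def _cut_positions(
    state: PairMatchState, pos: int, len1: int, len2: int
) -> tuple[int, int]:
    """Apply the adjacent-1-bp check per read and clamp to the read."""
    s1 = pos
    if pos <= len1 - 3:
        s1 = adjust_position(state.packed_r1, state.adapter1, pos)
    s2 = pos
    if pos <= len2 - 3:
        s2 = adjust_position(state.packed_r2, state.adapter2, pos)
    return min(max(s1, 0), len1), min(max(s2, 0), len2)


def decide(
    state: PairMatchState,
    r1: FastqRead,
    r2: FastqRead,
    trim_score: float = DEFAULT_TRIM_SCORE,
    tail_length: int = DEFAULT_TAIL_LENGTH,
    tail_filter_prose: bool = False,
) -> TrimVerdict:
    """Reconcile the four matches of a pair into a trim verdict."""
    len1, len2 = len(r1.bases), len(r2.bases)
    c1a, c1p = state.r1_adapter, state.r1_pe
    c2a, c2p = state.r2_adapter, state.r2_pe

    pos1, score1 = reconcile((c1a.insert_size, c1a.score), (c1p.insert_size, c1p.score))
    pos2, score2 = reconcile((c2a.insert_size, c2a.score), (c2p.insert_size, c2p.score))
    r12_pos, r12_score = reconcile((pos1, score1), (pos2, score2))

    # low-quality override: one confident read, the other unable to confirm
    if pos1 != pos2:
        if pos1 is not None and score1 > trim_score:
            too_short = len2 <= pos1
            if too_short or mean_16mer_prob(state.phred_r2, pos1, floor=False) < LOW_QUALITY_PROB:
                s1, s2 = _cut_positions(state, pos1, len1, len2)
                return TrimVerdict(True, s1, s2, score1, "low-quality-override")
        elif pos2 is not None and score2 > trim_score:
            too_short = len1 <= pos2
            if too_short or mean_16mer_prob(state.phred_r1, pos2, floor=False) < LOW_QUALITY_PROB:
                s1, s2 = _cut_positions(state, pos2, len1, len2)
                return TrimVerdict(True, s1, s2, score2, "low-quality-override")

    # tail false-positive filter
    def in_tail(c, length):
        return c.found and c.insert_size is not None and c.insert_size >= length - tail_length

    if tail_filter_prose:
        e1 = in_tail(c1a, len1) and not in_tail(c1p, len1)
        e2 = in_tail(c2a, len2) and not in_tail(c2p, len2)
    else:
        e1 = in_tail(c1a, len1) and in_tail(c1p, len1)
        e2 = in_tail(c2a, len2) and in_tail(c2p, len2)
    r1_same = c1a.found and c1p.found and c1a.insert_size == c1p.insert_size
    r2_same = c2a.found and c2p.found and c2a.insert_size == c2p.insert_size
    is_false_positive = (e1 or e2) and not (r1_same or r2_same)

    if r12_pos is not None and r12_score > trim_score:
        if is_false_positive:
            return TrimVerdict(False, len1, len2, r12_score, "rejected-tail-FP")
        s1, s2 = _cut_positions(state, r12_pos, len1, len2)
        reason = "agreed" if (pos1 is not None and pos1 == pos2) else "score-max"
        return TrimVerdict(True, s1, s2, r12_score, reason)
    return TrimVerdict(False, len1, len2, r12_score, "below-threshold")


def cut_pair(
    r1: FastqRead, r2: FastqRead, verdict: TrimVerdict
) -> tuple[FastqRead, FastqRead]:
    """Cut both reads (bases and qualities together) per the verdict."""
    if not verdict.trim:
        return r1, r2
    s1, s2 = verdict.insert_size_r1, verdict.insert_size_r2
    return (
        FastqRead(r1.id, r1.bases[:s1], r1.quals[:s1]),
        FastqRead(r2.id, r2.bases[:s2], r2.quals[:s2]),
    )
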