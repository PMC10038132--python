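"""Overlap consensus calling: prediction, assessment, correction.

When the insert is shorter than twice the read length, the mates overlap
on their shared insert and disagreements there can be repaired from the
higher-quality call.  Three steps:

1. *Prediction* — if adapters were trimmed and both mates now have the
   same length, the overlap equals that length.  Otherwise the head of
   each mate's reverse complement is matched into the other read; the
   prediction passes only when both matches are found and imply the same
   insert size (``s = offset + len(other read)``).
2. *Assessment* — the whole overlapped region is compared position by
   position with N converted to gap (so N counts as a mismatch); the pair
   passes when the mismatch fraction over the overlap length is at most
   ``max_mismatch_ratio`` (default 0.28).
3. *Correction* — at each disagreeing overlapped position both reads
   receive the call (complemented for read 2) with the higher Phred
   score, and the winning quality is copied to both; equal qualities keep
   read 1's call.  Read lengths never change.
"""

from __future__ import annotations

import numpy as np

from .decision import TrimVerdict
from .fastqio import FastqRead
from .packedseq import PackedSeq, complement_code, _CHAR_OF_CODE
from .wordmatch import scan

__all__ = [
    "predict_overlap",
    "assess_overlap",
    "correct_overlap",
    "consensus_call",
]

DEFAULT_MAX_MISMATCH_RATIO = 0.28


def _overlap_indices(s: int, len1: int, len2: int):
    """Index arrays of the overlapped region (r1 index i <-> r2 index s-1-i)."""
    lo = max(0, s - len2)
    hi = min(len1, s)
    if hi <= lo:
        return None, None
    idx1 = np.arange(lo, hi)
    idx2 = s - 1 - idx1
    return idx1, idx2


def predict_overlap(
    r1: FastqRead,
    r2: FastqRead,
    verdict: TrimVerdict | None,
    k: int = 2,
) -> tuple[bool, int | None]:
    """Predict whether the pair overlaps and at which insert size."""
    if verdict is not None and verdict.trim:
        if len(r1.bases) == len(r2.bases):
            return True, len(r1.bases)
        return False, None
    p1 = PackedSeq(r1.bases)
    p2 = PackedSeq(r2.bases)
    m1 = scan(p2.reverse_complement(), p1, k)  # rc(read2) head into read1
    m2 = scan(p1.reverse_complement(), p2, k)  # rc(read1) head into read2
    if not (m1.found and m2.found):
        return False, None
    s1 = m1.offset + len(r2.bases)
    s2 = m2.offset + len(r1.bases)
    if s1 != s2:
        return False, None
    return True, s1


def assess_overlap(
    r1: FastqRead,
    r2: FastqRead,
    s: int,
    max_mismatch_ratio: float = DEFAULT_MAX_MISMATCH_RATIO,
) -> bool:
    """Check the predicted overlap's mismatch fraction (N counts as mismatch)."""
    idx1, idx2 = _overlap_indices(s, len(r1.bases), len(r2.bases))
    if idx1 is None:
        return False
    c1 = PackedSeq(r1.bases).codes.copy()
    c2 = complement_code(PackedSeq(r2.bases).codes)
    c1[c1 == 15] = 0  # N -> gap before matching
    c2 = c2.copy()
    c2[c2 == 15] = 0
    mismatch = (c1[idx1] & c2[idx2]) == 0
    return float(mismatch.mean()) <= max_mismatch_ratio


def correct_overlap(
    r1: FastqRead, r2: FastqRead, s: int
) -> tuple[FastqRead, FastqRead]:
    """Replace disagreeing overlapped calls with the higher-quality call."""
    idx1, idx2 = _overlap_indices(s, len(r1.bases), len(r2.bases))
    if idx1 is None:
        return r1, r2
    p1 = PackedSeq(r1.bases)
    p2 = PackedSeq(r2.bases)
    codes1 = p1.codes.copy()
    codes2 = p2.codes.copy()
    q1 = np.frombuffer(r1.quals.encode("ascii"), dtype=np.uint8).copy()
    q2 = np.frombuffer(r2.quals.encode("ascii"), dtype=np.uint8).copy()

    c2_as_r1 = complement_code(codes2)  # read-2 calls in read-1 orientation
    disagree = codes1[idx1] != c2_as_r1[idx2]
    if disagree.any():
        d1 = idx1[disagree]
        d2 = idx2[disagree]
        r1_wins = q1[d1] >= q2[d2]  # ties keep read 1's call
        w1, w2 = d1[r1_wins], d2[r1_wins]
        codes2[w2] = complement_code(codes1[w1])
        q2[w2] = q1[w1]
        l1, l2 = d1[~r1_wins], d2[~r1_wins]
        codes1[l1] = complement_code(codes2[l2])
        q1[l1] = q2[l2]

    new_r1 = FastqRead(
        r1.id, _CHAR_OF_CODE[codes1].tobytes().decode("ascii"), q1.tobytes().decode("ascii")
    )
    new_r2 = FastqRead(
        r2.id, _CHAR_OF_CODE[codes2].tobytes().decode("ascii"), q2.tobytes().decode("ascii")
    )
    return new_r1, new_r2


def consensus_call(
    r1: FastqRead,
    r2: FastqRead,
    verdict: TrimVerdict | None,
    k: int = 2,
    max_mismatch_ratio: float = DEFAULT_MAX_MISMATCH_RATIO,
) -> tuple[FastqRead, FastqRead, bool]:
    """Run prediction, assessment and correction; report whether applied."""
    overlap, s = predict_overlap(r1, r2, verdict, k)
    if not overlap:
        return r1, r2, False
    if not assess_overlap(r1, r2, s, max_mismatch_ratio):
        return r1, r2, False
    new_r1, new_r2 = correct_overlap(r1, r2, s)
    return new_r1, new_r2, True
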