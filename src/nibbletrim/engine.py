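"""Four-way adapter / paired-end matching for one read pair.

Four 16-mer scans are run per pair: each adapter head against its read,
and each read head against the reverse complement of its mate.  All
results are expressed as insert-size candidates: an adapter starting at
read offset ``p`` means the insert occupies bases ``0..p-1`` (s = p), and
a read head found at offset ``p`` of the mate's reverse complement means
``s = len(mate) - p``.

If both adapter matches are weak (fewer matched bases than the cutoff),
the paired-end scans run with a loosened tolerance ``k + 1``.  If the best
of the four matches clears the cutoff, weak matches are re-evaluated with
tolerance-free counting at the single offset the best insert size implies,
and replaced when the re-count clears the cutoff — the loosened-k rescue.

Scores follow the quality-weighted model: adapter matches are weighted by
the read's mean 16-mer correctness probability at the insert size (adapter
probability = 1); paired-end matches additionally carry the mate head's
mean probability at position 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .fastqio import FastqRead
from .packedseq import PackedSeq
from .scoring import mean_16mer_prob, phred_array
from .wordmatch import match_at, scan

__all__ = ["MatchCandidate", "PairMatchState", "four_way_match"]

logger = logging.getLogger(__name__)

DEFAULT_K = 2
DEFAULT_CUTOFF = 9


@dataclass
class MatchCandidate:
    """One of the four matches, in insert-size coordinates."""

    insert_size: int | None  # None when not found
    n_match: int
    score: float
    found: bool


@dataclass
class PairMatchState:
    """The four reconciliation inputs plus cached per-pair context."""

    r1_adapter: MatchCandidate
    r2_adapter: MatchCandidate
    r1_pe: MatchCandidate
    r2_pe: MatchCandidate
    # cached context reused by the decision and consensus stages
    packed_r1: PackedSeq
    packed_r2: PackedSeq
    phred_r1: np.ndarray
    phred_r2: np.ndarray
    adapter1: PackedSeq
    adapter2: PackedSeq


def four_way_match(
    r1: FastqRead,
    r2: FastqRead,
    adapter1: PackedSeq,
    adapter2: PackedSeq,
    k: int = DEFAULT_K,
    cutoff: int = DEFAULT_CUTOFF,
) -> PairMatchState:
    """Run the four matches for one pair and score them."""
    if min(adapter1.n_bases, adapter2.n_bases) < 16:
        logger.warning(
            "adapter shorter than 16 bases; gap-padded head 16-mer used"
        )
    p1 = PackedSeq(r1.bases)
    p2 = PackedSeq(r2.bases)
    rc1 = p1.reverse_complement()
    rc2 = p2.reverse_complement()
    len1, len2 = p1.n_bases, p2.n_bases

    m1a = scan(adapter1, p1, k)
    m2a = scan(adapter2, p2, k)
    k_extra = 1 if max(m1a.n_match, m2a.n_match) < cutoff else 0
    m1p = scan(p1, rc2, k + k_extra)
    m2p = scan(p2, rc1, k + k_extra)

    # (name, raw MatchResult, query, subject, insert->offset mapping)
    entries = {
        "r1_adapter": (m1a, adapter1, p1, lambda s: s),
        "r2_adapter": (m2a, adapter2, p2, lambda s: s),
        "r1_pe": (m1p, p1, rc2, lambda s: len2 - s),
        "r2_pe": (m2p, p2, rc1, lambda s: len1 - s),
    }
    insert_of = {
        "r1_adapter": lambda off: off,
        "r2_adapter": lambda off: off,
        "r1_pe": lambda off: len2 - off,
        "r2_pe": lambda off: len1 - off,
    }

    cands: dict[str, MatchCandidate] = {}
    for name, (m, _q, _s, _map) in entries.items():
        s = insert_of[name](m.offset) if m.found else None
        cands[name] = MatchCandidate(s, m.n_match, 0.0, m.found)

    # loosened rescue at the best match's implied offset
    best_name = None
    best_nm = -1
    for name in ("r1_adapter", "r2_adapter", "r1_pe", "r2_pe"):
        c = cands[name]
        if c.found and c.n_match > best_nm:
            best_name, best_nm = name, c.n_match
    if best_name is not None and best_nm > cutoff:
        s_star = cands[best_name].insert_size
        for name, (m, query, subject, offset_of) in entries.items():
            c = cands[name]
            if c.found and c.n_match >= cutoff:
                continue
            implied = offset_of(s_star)
            if implied < 0:
                continue
            new_nm = match_at(query, subject, implied)
            if new_nm > cutoff:
                cands[name] = MatchCandidate(s_star, new_nm, 0.0, True)

    ph1 = phred_array(r1.quals)
    ph2 = phred_array(r2.quals)
    prob_head1 = mean_16mer_prob(ph1, 0)
    prob_head2 = mean_16mer_prob(ph2, 0)

    def adapter_score(c: MatchCandidate, ph: np.ndarray) -> float:
        if not c.found:
            return 0.0
        return c.n_match * mean_16mer_prob(ph, c.insert_size)

    def pe_score(c: MatchCandidate, ph: np.ndarray, mate_head_prob: float) -> float:
        if not c.found:
            return 0.0
        return c.n_match * mean_16mer_prob(ph, c.insert_size) * mate_head_prob

    cands["r1_adapter"].score = adapter_score(cands["r1_adapter"], ph1)
    cands["r2_adapter"].score = adapter_score(cands["r2_adapter"], ph2)
    cands["r1_pe"].score = pe_score(cands["r1_pe"], ph1, prob_head2)
    cands["r2_pe"].score = pe_score(cands["r2_pe"], ph2, prob_head1)

    return PairMatchState(
        r1_adapter=cands["r1_adapter"],
        r2_adapter=cands["r2_adapter"],
        r1_pe=cands["r1_pe"],
        r2_pe=cands["r2_pe"],
        packed_r1=p1,
        packed_r2=p2,
        phred_r1=ph1,
        phred_r2=ph2,
        adapter1=adapter1,
        adapter2=adapter2,
    )
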