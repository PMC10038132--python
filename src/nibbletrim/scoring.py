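"""Quality-weighted reliability scores for 16-mer matches.

A Phred score Q maps to the probability that the base call is correct,
P = 1 - 10^(-Q/10).  A 16-mer match is weighted by the mean P over its
window; because the k-mer scan already filters out unreliable hits, the
mean is floored at 0.75 so low-quality windows do not annihilate scores.
The score of a match is ``S = n_match * P̄_a * P̄_b`` (for a user-supplied
adapter, P̄ = 1), so S ranges over [0, 16].

Only Phred+33 qualities are supported.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "PROB_FLOOR",
    "base_prob",
    "phred_array",
    "mean_16mer_prob",
    "match_score",
]

PROB_FLOOR = 0.75

# correctness probability per Phred score, precomputed for speed
_PROB_OF_Q = 1.0 - 10.0 ** (-np.arange(128, dtype=np.float64) / 10.0)


def base_prob(q: float) -> float:
    """Probability that a base call with Phred score ``q`` is correct."""
    if q < 0:
        raise ValueError(f"Phred score must be non-negative, got {q}")
    return 1.0 - 10.0 ** (-q / 10.0)


def phred_array(quals: str) -> np.ndarray:
    """Decode a Phred+33 quality string to an integer score array."""
    return np.frombuffer(quals.encode("ascii"), dtype=np.uint8).astype(np.int64) - 33


def mean_16mer_prob(phred: np.ndarray, start: int, floor: bool = True) -> float:
    """Mean base-correctness probability of the 16-mer starting at ``start``.

    Only in-range bases enter the mean; a fully out-of-range window returns
    the 0.75 floor.  With ``floor=False`` the raw (unfloored) mean is
    returned, as used by the low-quality override in the decision rules.
    """
    if start < 0:
        raise ValueError(f"start must be non-negative, got {start}")
    window = phred[start : start + 16]
    if window.size == 0:
        return PROB_FLOOR
    p = float(_PROB_OF_Q[window].mean())
    if floor and p < PROB_FLOOR:
        return PROB_FLOOR
    return p


def match_score(n_match: int, p_a: float, p_b: float) -> float:
    """Matching score ``S = n_match * p_a * p_b`` in [0, 16]."""
    return n_match * p_a * p_b
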