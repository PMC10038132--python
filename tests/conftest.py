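"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from nibbletrim import DEFAULT_ADAPTER1, DEFAULT_ADAPTER2

# one-hot nibble codes, independent of the package's encoding tables
ORACLE_CODES = {
    "-": 0b0000, "A": 0b0001, "C": 0b0010, "M": 0b0011, "G": 0b0100,
    "R": 0b0101, "S": 0b0110, "V": 0b0111, "T": 0b1000, "W": 0b1001,
    "Y": 0b1010, "H": 0b1011, "K": 0b1100, "D": 0b1101, "B": 0b1110,
    "N": 0b1111,
}


def oracle_match_at(query: str, subject: str, offset: int) -> int:
    """Per-character matched-base count with the bitwise semantics.

    Even offsets compare query bases 0..15; odd offsets compare query
    bases 1..16 (the odd-offset window of the word-level scan).
    Out-of-range positions are gaps and share no bits with anything.
    """
    q_start = 0 if offset % 2 == 0 else 1
    s_start = offset + q_start
    bits = 0
    for j in range(16):
        qi, si = q_start + j, s_start + j
        ca = ORACLE_CODES[query[qi]] if qi < len(query) else 0
        cb = ORACLE_CODES[subject[si]] if si < len(subject) else 0
        bits += bin(ca & cb).count("1")
    return min(bits, 16)


def oracle_scan(query: str, subject: str, k: int):
    """Brute-force reference for the word scan: (offset, n_match, found)."""
    best_offset, best_nm = -1, -1
    for offset in range(len(subject)):
        nm = oracle_match_at(query, subject, offset)
        if nm > best_nm:
            best_offset, best_nm = offset, nm
    if best_offset < 0:
        return -1, 0, False
    return best_offset, best_nm, (16 - best_nm) <= k


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length)) if length else ""


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)


@pytest.fixture
def adapters() -> tuple[str, str]:
    return DEFAULT_ADAPTER1, DEFAULT_ADAPTER2
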