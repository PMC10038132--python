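"""4-bit packed DNA sequences with bit-safe tail padding.

Each base is a 4-bit one-hot code over the bit set {A=1, C=2, G=4, T=8};
IUPAC ambiguity codes are unions of those bits (N=1111, S=0110, ...) and the
gap is 0000.  Sixteen bases are packed per 64-bit word, base ``2n`` sitting
in the least-significant nibble of the word read at byte position ``n``
(one byte holds two bases, so only even base indices are byte-aligned).

A packed sequence is "bit-safe": one extra all-zero word is appended past
the last word holding bases, and every bit after base ``n_bases - 1`` is
zero.  Word-sized reads near the tail are therefore always legal and the
out-of-range nibbles decode as gaps.

Index convention: base indices are 0-based throughout; ranges quoted as
``a[i:j]`` in prose are inclusive of both ends only when explicitly written
``i..j``, otherwise Python half-open slicing applies.
"""

from __future__ import annotations

import numpy as np

__all__ = ["PackedSeq", "encode", "complement_code"]

_MASK64 = (1 << 64) - 1

# one-hot nibble codes indexed by IUPAC character; gap is '-' (or '.')
_CODE_CHARS = b"-ACMGRSVTWYHKDBN"
_CHAR_OF_CODE = np.frombuffer(_CODE_CHARS, dtype=np.uint8)

_CODE_OF_CHAR = np.full(256, 0xFF, dtype=np.uint8)
for _code, _ch in enumerate(_CODE_CHARS):
    _CODE_OF_CHAR[_ch] = _code
    _CODE_OF_CHAR[ord(chr(_ch).lower())] = _code
_CODE_OF_CHAR[ord(".")] = 0

# complement of a one-hot nibble is its 4-bit reversal (A<->T, C<->G)
_COMP_CODE = np.array(
    [0, 8, 4, 12, 2, 10, 6, 14, 1, 9, 5, 13, 3, 11, 7, 15], dtype=np.uint8
)

_NIBBLE_SHIFTS = (np.arange(16, dtype=np.uint64) * np.uint64(4))


def complement_code(codes: np.ndarray) -> np.ndarray:
    """Complement an array of 4-bit base codes (A<->T, C<->G, N->N, gap->gap)."""
    return _COMP_CODE[codes]


def _pack(codes: np.ndarray) -> np.ndarray:
    """Pack 4-bit codes into uint64 words, appending one all-zero pad word."""
    n = codes.size
    n_words = (n + 15) // 16 + 1
    padded = np.zeros(16 * n_words, dtype=np.uint64)
    padded[:n] = codes
    return np.bitwise_or.reduce(
        padded.reshape(n_words, 16) << _NIBBLE_SHIFTS, axis=1
    )


class PackedSeq:
    """A DNA sequence packed 4 bits per base into 64-bit words.

    Parameters
    ----------
    seq
        DNA string over the IUPAC alphabet plus gap (``-`` or ``.``),
        case-insensitive.  Unknown characters are rejected.
    """

    __slots__ = ("codes", "words", "n_bases", "_byte_words")

    def __init__(self, seq: str | np.ndarray):
        if isinstance(seq, np.ndarray):
            codes = np.ascontiguousarray(seq, dtype=np.uint8)
        else:
            raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            codes = _CODE_OF_CHAR[raw]
            if codes.size and codes.max() == 0xFF:
                bad = int(np.argmax(codes == 0xFF))
                raise ValueError(
                    f"unknown DNA character {seq[bad]!r} at position {bad}"
                )
        self.codes = codes
        self.n_bases = int(codes.size)
        self.words = _pack(codes)
        self._byte_words = None

    @classmethod
    def _from_codes(cls, codes: np.ndarray) -> "PackedSeq":
        return cls(codes)

    def __len__(self) -> int:
        return self.n_bases

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        s = self.decode()
        if len(s) > 40:
            s = s[:37] + "..."
        return f"PackedSeq({s!r}, n_bases={self.n_bases})"

    def decode(self) -> str:
        """Decode back to an uppercase IUPAC string."""
        return _CHAR_OF_CODE[self.codes].tobytes().decode("ascii")

    @property
    def byte_words(self) -> np.ndarray:
        """uint64 words read at every byte position of the packed buffer.

        ``byte_words[n]`` covers bases ``2n .. 2n+15``; positions past the
        sequence end read as gaps thanks to the bit-safe padding.
        """
        if self._byte_words is None:
            b = self.words.view(np.uint8)  # little-endian nibble/byte layout
            win = np.lib.stride_tricks.sliding_window_view(b, 8)
            self._byte_words = np.ascontiguousarray(win).view(np.uint64).ravel()
        return self._byte_words

    def word_at(self, n: int) -> int:
        """The 64-bit word at byte position ``n`` (bases ``2n .. 2n+15``).

        Reads beyond the base range but inside the padded buffer are legal
        and return gap nibbles; addressing entirely past the padded buffer
        is an error.
        """
        bw = self.byte_words
        if not 0 <= n < bw.size:
            raise IndexError(
                f"byte position {n} is outside the padded buffer (0..{bw.size - 1})"
            )
        return int(bw[n])

    def head_pair(self) -> tuple[int, int]:
        """``(a0, a_minus)``: the head 16-mers at base offsets 0 and 1.

        ``a0`` covers bases 0..15 and ``a_minus`` bases 1..16, via
        ``a_minus = (a0 >> 4) | (a1 << 4)`` where ``a1`` is the word at
        byte position 1.
        """
        a0 = self.word_at(0)
        a1 = self.word_at(1) if self.byte_words.size > 1 else 0
        a_minus = ((a0 >> 4) | (a1 << 4)) & _MASK64
        return a0, a_minus

    def reverse_complement(self) -> "PackedSeq":
        """Reverse-complemented copy (A<->T, C<->G, N->N, gap->gap)."""
        return PackedSeq._from_codes(_COMP_CODE[self.codes][::-1])


def encode(sequence: str) -> PackedSeq:
    """Encode a DNA string into a :class:`PackedSeq`."""
    return PackedSeq(sequence)
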