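"""FASTQ records, paired streaming I/O and gzip support.

Only 4-line FASTQ records with Phred+33 qualities are handled.  Gzip input
is auto-detected from the magic bytes; output compression is explicit.
Paired files are checked for synchronization: read IDs are compared up to
the first whitespace with a trailing ``/1`` or ``/2`` stripped.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from typing import IO, Iterable, Iterator

__all__ = ["FastqRead", "open_maybe_gzip", "read_pairs", "write_pairs"]


@dataclass
class FastqRead:
    """One FASTQ record: identifier, bases and Phred+33 quality string."""

    id: str
    bases: str
    quals: str

    def __len__(self) -> int:
        return len(self.bases)


def open_maybe_gzip(path: str, mode: str = "rt") -> IO[str]:
    """Open ``path`` for text reading, transparently decoding gzip."""
    if "r" in mode:
        with open(path, "rb") as fh:
            magic = fh.read(2)
        if magic == b"\x1f\x8b":
            return gzip.open(path, "rt")
        return open(path, "rt")
    raise ValueError("open_maybe_gzip is read-only; use _open_out for writing")


def _open_out(path: str, compress: bool) -> IO[str]:
    if compress:
        # fixed mtime for byte-stable output across runs
        raw = open(path, "wb")
        return io.TextIOWrapper(gzip.GzipFile(fileobj=raw, mode="wb", mtime=0))
    return open(path, "wt")


def _parse_fastq(handle: IO[str], path: str) -> Iterator[FastqRead]:
    line_no = 0
    while True:
        header = handle.readline()
        if not header:
            return
        bases = handle.readline()
        plus = handle.readline()
        quals = handle.readline()
        line_no += 4
        if not quals:
            raise ValueError(f"{path}: truncated FASTQ record at line {line_no - 3}")
        header, bases, plus, quals = (
            header.rstrip("\n"), bases.rstrip("\n"), plus.rstrip("\n"), quals.rstrip("\n"),
        )
        if not header.startswith("@"):
            raise ValueError(
                f"{path}: line {line_no - 3}: expected '@' header, got {header[:20]!r}"
            )
        if not plus.startswith("+"):
            raise ValueError(
                f"{path}: line {line_no - 1}: expected '+' separator, got {plus[:20]!r}"
            )
        if len(bases) != len(quals):
            raise ValueError(
                f"{path}: line {line_no - 3}: sequence and quality lengths differ "
                f"({len(bases)} vs {len(quals)})"
            )
        if not header[1:]:
            raise ValueError(f"{path}: line {line_no - 3}: empty read identifier")
        yield FastqRead(header[1:], bases, quals)


def _pair_key(identifier: str) -> str:
    key = identifier.split()[0] if identifier.split() else identifier
    if key.endswith("/1") or key.endswith("/2"):
        key = key[:-2]
    return key


def read_pairs(path1: str, path2: str) -> Iterator[tuple[FastqRead, FastqRead]]:
    """Yield synchronized read pairs from two (possibly gzipped) FASTQ files.

    Desynchronized files — mismatched record counts or IDs that disagree
    after ``/1``/``/2`` normalization — raise a hard error naming the pair
    index.
    """
    with open_maybe_gzip(path1) as h1, open_maybe_gzip(path2) as h2:
        it1 = _parse_fastq(h1, path1)
        it2 = _parse_fastq(h2, path2)
        index = 0
        while True:
            r1 = next(it1, None)
            r2 = next(it2, None)
            index += 1
            if r1 is None and r2 is None:
                return
            if r1 is None or r2 is None:
                short = path1 if r1 is None else path2
                raise ValueError(f"{short}: ran out of records at pair {index}")
            if _pair_key(r1.id) != _pair_key(r2.id):
                raise ValueError(
                    f"paired files desynchronized at pair {index}: "
                    f"{r1.id!r} vs {r2.id!r}"
                )
            yield r1, r2


def write_pairs(
    stream: Iterable[tuple[FastqRead, FastqRead]],
    out1: str,
    out2: str,
    compress: bool = False,
) -> dict:
    """Write read pairs as 4-line FASTQ; return a count summary."""
    written = 0
    with _open_out(out1, compress) as h1, _open_out(out2, compress) as h2:
        for r1, r2 in stream:
            h1.write(f"@{r1.id}\n{r1.bases}\n+\n{r1.quals}\n")
            h2.write(f"@{r2.id}\n{r2.bases}\n+\n{r2.quals}\n")
            written += 1
    return {"pairs_written": written}
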