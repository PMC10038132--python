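"""Base-by-base paired-end read simulator with an indel/substitution profile.

The simulator mimics sequencing-by-synthesis: a random ACGT insert of a
chosen size is drawn, the two templates ``insert + adapter1`` and
``reverse_complement(insert) + adapter2`` are built, and each template is
copied base by base.  At every template base a deletion skips it, an
insertion emits one uniform random base before it, and a substitution
replaces it with a uniform different base.  Copying continues with uniform
random filler after the template until the read length is reached; reads
longer than the budget are truncated.

The truth record tracks, through indels, where the adapter region starts
in each final read (the number of bases emitted while copying the insert
section, clamped to the read length); a value equal to the read length
means no adapter base survives in the read.

The baseline error profile is 0.1% substitutions, 0.001% insertions and
0.001% deletions per base; the benchmark grid scales it 1-5x, crosses
adapter lengths 16/20/24/28/33 (prefixes of the default adapter pair)
with even insert sizes 66-120 at 100 bp reads, and simulates a fixed
number of pairs per condition.

Simulated qualities are a constant Phred score (Q30 by default; the
quality-dependent machinery of the trimmer is inert unless lowered).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .fastqio import FastqRead, _open_out
from .pipeline import DEFAULT_ADAPTER1, DEFAULT_ADAPTER2

__all__ = [
    "ErrorProfile",
    "SimTruth",
    "simulate_pair",
    "iter_grid",
    "simulate_grid",
    "TRUTH_COLUMNS",
]

BASELINE_SUB_RATE = 0.001
BASELINE_INS_RATE = 0.00001
BASELINE_DEL_RATE = 0.00001

_IDX_TO_CHAR = np.frombuffer(b"ACGT", dtype=np.uint8)
_CHAR_TO_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}

TRUTH_COLUMNS = (
    "pair_id",
    "insert_size",
    "adapter_len",
    "profile_multiplier",
    "read_length",
    "true_trim_pos_r1",
    "true_trim_pos_r2",
)


@dataclass(frozen=True)
class ErrorProfile:
    """Per-base substitution/insertion/deletion probabilities."""

    sub_rate: float = BASELINE_SUB_RATE
    ins_rate: float = BASELINE_INS_RATE
    del_rate: float = BASELINE_DEL_RATE

    def __post_init__(self) -> None:
        for name in ("sub_rate", "ins_rate", "del_rate"):
            rate = getattr(self, name)
            if not 0 <= rate < 1:
                raise ValueError(f"{name} must be in [0, 1), got {rate}")

    @classmethod
    def baseline(cls, multiplier: float = 1.0) -> "ErrorProfile":
        """The baseline Illumina-like profile scaled by ``multiplier``."""
        return cls(
            BASELINE_SUB_RATE * multiplier,
            BASELINE_INS_RATE * multiplier,
            BASELINE_DEL_RATE * multiplier,
        )


@dataclass(frozen=True)
class SimTruth:
    """Ground truth for one simulated pair."""

    original_insert_size: int
    adapter_length: int
    read_length: int
    true_trim_pos_r1: int
    true_trim_pos_r2: int


def _seq_to_idx(seq: str) -> np.ndarray:
    return np.array([_CHAR_TO_IDX[ch] for ch in seq.upper()], dtype=np.int8)


def _copy_template(
    template: np.ndarray,
    insert_len: int,
    read_length: int,
    profile: ErrorProfile,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """Copy one template with errors; return (read base indices, adapter start)."""
    t = template.size
    draws = rng.random((3, t))
    deleted = draws[0] < profile.del_rate
    inserted = draws[1] < profile.ins_rate
    substituted = draws[2] < profile.sub_rate
    kept = ~deleted

    emitted = template.copy()
    sub_mask = substituted & kept
    n_sub = int(sub_mask.sum())
    if n_sub:
        emitted[sub_mask] = (
            emitted[sub_mask] + rng.integers(1, 4, n_sub, dtype=np.int8)
        ) % 4

    counts = kept.astype(np.int64) + inserted
    ends = np.cumsum(counts)
    total = int(ends[-1]) if t else 0
    out = np.empty(total, dtype=np.int8)
    out[ends[kept] - 1] = emitted[kept]
    n_ins = int(inserted.sum())
    if n_ins:
        out[ends[inserted] - 1 - kept[inserted]] = rng.integers(
            0, 4, n_ins, dtype=np.int8
        )

    insert_emitted = int(ends[insert_len - 1]) if 0 < insert_len <= t else 0
    if total < read_length:
        filler = rng.integers(0, 4, read_length - total, dtype=np.int8)
        out = np.concatenate([out, filler])
    else:
        out = out[:read_length]
    return out, min(insert_emitted, read_length)


def simulate_pair(
    insert_size: int,
    read_length: int,
    adapter1: str,
    adapter2: str,
    profile: ErrorProfile,
    rng: np.random.Generator,
    quality: int = 30,
) -> tuple[FastqRead, FastqRead, SimTruth]:
    """Simulate one read pair from a fresh random insert."""
    if insert_size < 1 or read_length < 1:
        raise ValueError("insert_size and read_length must be >= 1")
    insert = rng.integers(0, 4, insert_size, dtype=np.int8)
    ad1 = _seq_to_idx(adapter1)
    ad2 = _seq_to_idx(adapter2)
    template1 = np.concatenate([insert, ad1])
    template2 = np.concatenate([(3 - insert)[::-1], ad2])

    bases1, trim1 = _copy_template(template1, insert_size, read_length, profile, rng)
    bases2, trim2 = _copy_template(template2, insert_size, read_length, profile, rng)

    quals = chr(33 + quality) * read_length
    r1 = FastqRead("sim", _IDX_TO_CHAR[bases1].tobytes().decode("ascii"), quals)
    r2 = FastqRead("sim", _IDX_TO_CHAR[bases2].tobytes().decode("ascii"), quals)
    truth = SimTruth(insert_size, len(adapter1), read_length, trim1, trim2)
    return r1, r2, truth


def iter_grid(
    profiles: Sequence[float] = (1, 2, 3, 4, 5),
    adapter_lengths: Sequence[int] = (16, 20, 24, 28, 33),
    insert_sizes: Sequence[int] = tuple(range(66, 121, 2)),
    pairs_per_condition: int = 30000,
    read_length: int = 100,
    adapter1: str = DEFAULT_ADAPTER1,
    adapter2: str = DEFAULT_ADAPTER2,
    seed: int = 1,
    quality: int = 30,
) -> Iterator[tuple[FastqRead, FastqRead, SimTruth, dict]]:
    """Fully cross the condition grid; a pure function of seed and config.

    ``profiles`` are multipliers of the baseline error profile, and
    ``adapter_lengths`` select prefixes of the configured adapters.
    Yields ``(r1, r2, truth, row)`` with ``row`` being the truth-table
    record (including the unique pair id, also set as the read id).
    """
    rng = np.random.default_rng(seed)
    for mult in profiles:
        profile = ErrorProfile.baseline(mult)
        for alen in adapter_lengths:
            a1 = adapter1[:alen]
            a2 = adapter2[:alen]
            for insert_size in insert_sizes:
                for i in range(pairs_per_condition):
                    r1, r2, truth = simulate_pair(
                        insert_size, read_length, a1, a2, profile, rng, quality
                    )
                    pair_id = f"sim_p{mult:g}_a{alen}_s{insert_size}_{i}"
                    r1.id = f"{pair_id}/1"
                    r2.id = f"{pair_id}/2"
                    row = {
                        "pair_id": pair_id,
                        "insert_size": insert_size,
                        "adapter_len": alen,
                        "profile_multiplier": mult,
                        "read_length": read_length,
                        "true_trim_pos_r1": truth.true_trim_pos_r1,
                        "true_trim_pos_r2": truth.true_trim_pos_r2,
                    }
                    yield r1, r2, truth, row


def simulate_grid(
    out1: str,
    out2: str,
    truth_path: str,
    compress: bool = False,
    **grid_kwargs,
) -> int:
    """Write the simulation grid as a FASTQ pair plus a truth TSV.

    Returns the number of pairs written.  Reproducible: the same seed and
    configuration produce byte-identical outputs.
    """
    n = 0
    with _open_out(out1, compress) as h1, _open_out(out2, compress) as h2, open(
        truth_path, "wt"
    ) as ht:
        ht.write("\t".join(TRUTH_COLUMNS) + "\n")
        for r1, r2, _truth, row in iter_grid(**grid_kwargs):
            h1.write(f"@{r1.id}\n{r1.bases}\n+\n{r1.quals}\n")
            h2.write(f"@{r2.id}\n{r2.bases}\n+\n{r2.quals}\n")
            ht.write("\t".join(str(row[c]) for c in TRUTH_COLUMNS) + "\n")
            n += 1
    return n
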