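"""Trimming-accuracy evaluation against a simulation truth table.

Every read (two per pair) is scored independently: a trim is *correct*
when the trimmed length equals the true adapter start exactly.  Reads are
split by adapter presence (true position < read length):

* adapter-bearing reads: TP when trimmed correctly, FN otherwise;
* adapter-free reads: TN when left fully intact, FP otherwise.

From the contingency table: PPV = TP/(TP+FP), sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP) and the Matthews correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FN)(TN+FP))

with the convention MCC = 0 when any denominator factor is zero.  Signed
length differences additionally classify reads as accurate, 1-bp or
multi-bp over-/under-trimmed (over = trimmed shorter than the truth).
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .fastqio import open_maybe_gzip

__all__ = ["TrimMetrics", "mcc", "evaluate_lengths", "evaluate"]


@dataclass(frozen=True)
class TrimMetrics:
    """Confusion counts, derived rates and trim-accuracy classes."""

    tp: int
    tn: int
    fp: int
    fn: int
    ppv: float
    sensitivity: float
    specificity: float
    mcc: float
    n_reads: int
    n_adapter: int
    n_adapter_free: int
    accurate: int
    over_1bp: int
    under_1bp: int
    over_multi: int
    under_multi: int

    def as_dict(self) -> dict:
        return asdict(self)


def mcc(tp: int, tn: int, fp: int, fn: int) -> float:
    """Matthews correlation coefficient; 0 when a denominator factor is 0."""
    denom = (tp + fp) * (tp + fn) * (tn + fn) * (tn + fp)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def _rate(num: int, denom: int) -> float:
    return num / denom if denom else 0.0


def evaluate_lengths(
    trimmed_len: np.ndarray, true_pos: np.ndarray, read_length: np.ndarray
) -> TrimMetrics:
    """Score per-read trimmed lengths against true adapter starts."""
    trimmed_len = np.asarray(trimmed_len)
    true_pos = np.asarray(true_pos)
    read_length = np.asarray(read_length)
    diff = trimmed_len - true_pos
    bearing = true_pos < read_length
    accurate = diff == 0
    intact = trimmed_len == read_length

    tp = int((bearing & accurate).sum())
    fn = int((bearing & ~accurate).sum())
    tn = int((~bearing & intact).sum())
    fp = int((~bearing & ~intact).sum())

    return TrimMetrics(
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
        ppv=_rate(tp, tp + fp),
        sensitivity=_rate(tp, tp + fn),
        specificity=_rate(tn, tn + fp),
        mcc=mcc(tp, tn, fp, fn),
        n_reads=int(diff.size),
        n_adapter=int(bearing.sum()),
        n_adapter_free=int((~bearing).sum()),
        accurate=int(accurate.sum()),
        over_1bp=int((diff == -1).sum()),
        under_1bp=int((diff == 1).sum()),
        over_multi=int((diff <= -2).sum()),
        under_multi=int((diff >= 2).sum()),
    )


def _trimmed_lengths(path: str) -> tuple[list[str], np.ndarray]:
    ids: list[str] = []
    lengths: list[int] = []
    with open_maybe_gzip(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            bases = fh.readline().rstrip("\n")
            fh.readline()
            fh.readline()
            ids.append(header.rstrip("\n")[1:].split()[0])
            lengths.append(len(bases))
    return ids, np.array(lengths, dtype=np.int64)


def evaluate(trimmed1: str, trimmed2: str, truth_path: str) -> TrimMetrics:
    """Evaluate a trimmed FASTQ pair against the simulator's truth table.

    The trimmer must preserve read order and identifiers; any mismatch
    with the truth table is a hard error.
    """
    truth = pd.read_csv(truth_path, sep="\t")
    ids1, len1 = _trimmed_lengths(trimmed1)
    ids2, len2 = _trimmed_lengths(trimmed2)
    if len(ids1) != len(truth) or len(ids2) != len(truth):
        raise ValueError(
            f"record count mismatch: truth has {len(truth)} pairs, trimmed files "
            f"have {len(ids1)} and {len(ids2)}"
        )
    expected = truth["pair_id"].astype(str).to_numpy()
    for mate, ids in ((1, ids1), (2, ids2)):
        got = np.array([i[:-2] if i.endswith(("/1", "/2")) else i for i in ids])
        bad = got != expected
        if bad.any():
            idx = int(np.argmax(bad))
            raise ValueError(
                f"read {idx} of mate {mate} has id {ids[idx]!r}; "
                f"truth expects {expected[idx]!r}"
            )
    trimmed_len = np.concatenate([len1, len2])
    true_pos = np.concatenate(
        [truth["true_trim_pos_r1"].to_numpy(), truth["true_trim_pos_r2"].to_numpy()]
    )
    read_length = np.concatenate(
        [truth["read_length"].to_numpy(), truth["read_length"].to_numpy()]
    )
    return evaluate_lengths(trimmed_len, true_pos, read_length)
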