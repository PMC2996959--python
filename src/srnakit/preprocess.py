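"""Read collapsing, size selection and length/redundancy statistics.

Deep-sequenced small-RNA libraries are collapsed to unique sequences, each
carrying its redundant count, then restricted to the 18-30 nt size window
used throughout plant miRNA analysis.  The per-length unique/redundant
profile (and its redundancy ratio) is the standard first-look summary of a
library's composition.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Sequence

import pandas as pd

from .errors import ValidationError
from .io import SequenceRecord, SmallRNARead

DEFAULT_MIN_LEN = 18
DEFAULT_MAX_LEN = 30


def collapse_reads(raw: Iterable[SequenceRecord | str]) -> list[SmallRNARead]:
    """Collapse raw reads to unique sequences with redundant counts.

    Output is sorted by descending count, ties broken lexicographically by
    sequence, so collapsed files are reproducible.  Counts sum to the raw
    read total.
    """
    counter: Counter[str] = Counter()
    for rec in raw:
        counter[rec if isinstance(rec, str) else rec.seq] += 1
    reads = [SmallRNARead(seq, n) for seq, n in counter.items()]
    reads.sort(key=lambda r: (-r.count, r.seq))
    return reads


def collapse_counted(reads: Iterable[SmallRNARead]) -> list[SmallRNARead]:
    """Re-collapse already-counted reads (idempotent on collapsed input)."""
    counter: Counter[str] = Counter()
    for read in reads:
        counter[read.seq] += read.count
    out = [SmallRNARead(seq, n) for seq, n in counter.items()]
    out.sort(key=lambda r: (-r.count, r.seq))
    return out


def filter_by_length(
    reads: Sequence[SmallRNARead],
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> tuple[list[SmallRNARead], list[SmallRNARead]]:
    """Partition reads into (kept, discarded) by inclusive length bounds."""
    if min_len > max_len:
        raise ValidationError(f"min_len {min_len} > max_len {max_len}")
    kept, discarded = [], []
    for read in reads:
        (kept if min_len <= len(read) <= max_len else discarded).append(read)
    return kept, discarded


def length_distribution(
    reads: Sequence[SmallRNARead],
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> pd.DataFrame:
    """Per-length unique/redundant counts and redundancy ratio.

    Returns a DataFrame indexed by length over the full [min_len, max_len]
    range (zero rows included).  ``redundancy_ratio`` is redundant/unique,
    NaN where no unique read of that length exists.  Reads outside the range
    violate the precondition and raise.
    """
    unique: Counter[int] = Counter()
    redundant: Counter[int] = Counter()
    for read in reads:
        L = len(read)
        if not min_len <= L <= max_len:
            raise ValidationError(
                f"read of length {L} outside [{min_len}, {max_len}]"
            )
        unique[L] += 1
        redundant[L] += read.count
    lengths = list(range(min_len, max_len + 1))
    df = pd.DataFrame(
        {
            "unique_count": [unique[L] for L in lengths],
            "redundant_count": [redundant[L] for L in lengths],
        },
        index=pd.Index(lengths, name="length"),
    )
    df["redundancy_ratio"] = df["redundant_count"] / df["unique_count"].where(
        df["unique_count"] > 0
    )
    return df
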