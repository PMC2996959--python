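"""Annotation of collapsed reads against ncRNA reference classes.

Reads are partitioned into ncRNA classes (rRNA, tRNA, snRNA, snoRNA, exon,
intron, repeat) by priority-ordered exact substring matching against
per-class reference FASTA sets, after removing polyA artifacts.  Matching is
full-read, ungapped and orientation-agnostic (reference strand and its
reverse complement), the strictest reproducible reading of
database-comparison filtering.  Reads hitting nothing are "unannotated" and
flow to the miRNA modules downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigError
from .io import SequenceRecord, SmallRNARead, read_sequences, reverse_complement

#: Every label a read can receive, in canonical report order.
ANNOTATION_CLASSES = (
    "rRNA",
    "tRNA",
    "snRNA",
    "snoRNA",
    "exon",
    "intron",
    "repeat",
    "known_miRNA",
    "novel_candidate",
    "polyA_artifact",
    "unannotated",
)

#: Classes that may carry reference FASTA sets.
REFERENCE_CLASSES = ("rRNA", "tRNA", "snRNA", "snoRNA", "exon", "intron", "repeat")

DEFAULT_PRIORITY = list(REFERENCE_CLASSES)

#: A read is a polyA artifact when at least this fraction of it is A ...
POLYA_FRACTION = 0.9
#: ... or its 3' end is a run of at least this many consecutive A.
POLYA_TAIL_RUN = 10


@dataclass
class ReferenceIndex:
    """Substring-membership index over per-class reference sequence sets.

    Each class stores one concatenated haystack (references and their
    reverse complements joined with a separator absent from the RNA
    alphabet), so a membership query is a single C-level substring search.
    """

    classes: dict[str, str] = field(default_factory=dict)

    @classmethod
    def build(
        cls, class_refs: Mapping[str, Sequence[SequenceRecord]]
    ) -> "ReferenceIndex":
        index = cls()
        for label, refs in class_refs.items():
            if label not in REFERENCE_CLASSES:
                raise ConfigError(
                    f"unknown annotation class {label!r}; "
                    f"expected one of {REFERENCE_CLASSES}"
                )
            parts: list[str] = []
            for ref in refs:
                parts.append(ref.seq)
                parts.append(reverse_complement(ref.seq))
            index.classes[label] = "#".join(parts)
        return index

    @classmethod
    def from_fastas(cls, class_fastas: Mapping[str, str | Path]) -> "ReferenceIndex":
        return cls.build(
            {label: read_sequences(path) for label, path in class_fastas.items()}
        )

    def contains(self, label: str, seq: str) -> bool:
        """True iff ``seq`` occurs in any reference of ``label`` (either strand)."""
        haystack = self.classes.get(label)
        return haystack is not None and seq in haystack


def is_polyA_artifact(
    seq: str,
    a_fraction: float = POLYA_FRACTION,
    tail_run: int = POLYA_TAIL_RUN,
) -> bool:
    """PolyA artifact test: overall A fraction or terminal 3' A-run."""
    if not seq:
        return False
    if seq.count("A") / len(seq) >= a_fraction:
        return True
    run = len(seq) - len(seq.rstrip("A"))
    return run >= tail_run


def classify_read(
    read: SmallRNARead,
    index: ReferenceIndex,
    priority: Sequence[str] | None = None,
    a_fraction: float = POLYA_FRACTION,
    tail_run: int = POLYA_TAIL_RUN,
) -> str:
    """Assign the read to its first matching class in priority order.

    The polyA test runs first; then classes are tried in the given priority
    order (default rRNA > tRNA > snRNA > snoRNA > exon > intron > repeat);
    a read matching no reference is "unannotated".  The decision depends
    only on the read itself, so input order never changes any label.
    """
    priority = list(priority) if priority is not None else DEFAULT_PRIORITY
    unknown = [p for p in priority if p not in REFERENCE_CLASSES]
    if unknown:
        raise ConfigError(f"priority contains unknown classes {unknown!r}")
    if is_polyA_artifact(read.seq, a_fraction, tail_run):
        return "polyA_artifact"
    for label in priority:
        if index.contains(label, read.seq):
            return label
    return "unannotated"


def annotation_summary(
    classified: Iterable[tuple[SmallRNARead, str]]
) -> pd.DataFrame:
    """Per-class unique/redundant tallies with a grand Total row.

    The rows partition the library: class sums equal library totals.
    """
    uniq = {label: 0 for label in ANNOTATION_CLASSES}
    redn = {label: 0 for label in ANNOTATION_CLASSES}
    for read, label in classified:
        if label not in uniq:
            raise ConfigError(f"unknown class label {label!r}")
        uniq[label] += 1
        redn[label] += read.count
    rows = list(ANNOTATION_CLASSES) + ["Total"]
    uniq["Total"] = sum(uniq[c] for c in ANNOTATION_CLASSES)
    redn["Total"] = sum(redn[c] for c in ANNOTATION_CLASSES)
    return pd.DataFrame(
        {
            "unique_reads": [uniq[r] for r in rows],
            "redundant_reads": [redn[r] for r in rows],
        },
        index=pd.Index(rows, name="class"),
    )
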