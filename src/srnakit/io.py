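"""Sequence and table I/O.

All sequences are handled internally as RNA (``T`` is normalized to ``U`` on
read); records remember whether the original file used the DNA alphabet so
that writing round-trips the original lettering.  Small-RNA libraries use a
collapsed-FASTA dialect in which each header is ``<id>_<count>`` with
``count`` the number of redundant reads the unique sequence represents,
e.g. ``>sr1_42``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .errors import FormatError, ParseError, ValidationError

RNA_ALPHABET = set("ACGUN")

_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")


def normalize_rna(seq: str) -> str:
    """Uppercase a nucleotide string and convert T to U.

    Idempotent: applying it twice equals applying it once.
    """
    return seq.upper().replace("T", "U")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an RNA string (A<->U, G<->C, N->N)."""
    return normalize_rna(seq).translate(_COMPLEMENT)[::-1]


def gc_percent(seq: str) -> float:
    s = normalize_rna(seq)
    if not s:
        return 0.0
    return 100.0 * sum(1 for c in s if c in "GC") / len(s)


def au_percent(seq: str) -> float:
    s = normalize_rna(seq)
    if not s:
        return 0.0
    return 100.0 * sum(1 for c in s if c in "AU") / len(s)


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence, stored as RNA.

    ``dna`` records whether the source file used T so that writing restores
    the original alphabet.
    """

    id: str
    seq: str
    dna: bool = False

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValidationError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - RNA_ALPHABET
        if bad:
            raise ValidationError(
                f"record {self.id!r}: invalid characters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class SmallRNARead:
    """A unique small-RNA sequence with its redundant read count."""

    seq: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValidationError(f"read {self.seq!r}: count must be >= 1")
        if not self.seq:
            raise ValidationError("read with empty sequence")

    def __len__(self) -> int:
        return len(self.seq)


def read_sequences(path: str | Path, format: str = "fasta") -> list[SequenceRecord]:
    """Read FASTA or FASTQ records (qualities ignored) in file order.

    Lowercase is accepted and uppercased; T is normalized to U.  Duplicate
    identifiers within one file are rejected.
    """
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {format!r}")
    path = Path(path)
    records: list[SequenceRecord] = []
    seen_ids: set[str] = set()
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), format)):
            raw = str(rec.seq)
            if rec.id in seen_ids:
                raise ParseError(f"{path}: duplicate record id {rec.id!r}")
            seen_ids.add(rec.id)
            dna = "T" in raw.upper()
            try:
                records.append(SequenceRecord(rec.id, normalize_rna(raw), dna=dna))
            except ValidationError as exc:
                raise ParseError(f"{path}: record {i + 1}: {exc}") from exc
    except ValueError as exc:  # Biopython parse failure
        line = _offending_line(path, format)
        raise ParseError(f"{path}: malformed {format} near line {line}: {exc}") from exc
    return records


def _offending_line(path: Path, format: str) -> int:
    """Best-effort line number of the first structural violation."""
    try:
        with open(path) as fh:
            if format == "fasta":
                for n, line in enumerate(fh, 1):
                    if line.strip():
                        return n if not line.startswith(">") else n
            else:
                for n, line in enumerate(fh, 1):
                    if (n - 1) % 4 == 0 and not line.startswith("@"):
                        return n
                    if (n - 1) % 4 == 2 and not line.startswith("+"):
                        return n
    except OSError:
        pass
    return 1


def write_sequences(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write FASTA, restoring T for records read from DNA files."""
    with open(path, "w") as fh:
        for rec in records:
            seq = rec.seq.replace("U", "T") if rec.dna else rec.seq
            fh.write(f">{rec.id}\n{seq}\n")


def read_collapsed_fasta(path: str | Path) -> list[SmallRNARead]:
    """Read a collapsed small-RNA FASTA (``>id_count`` headers).

    Duplicate sequences are rejected: a collapsed set holds each unique
    sequence exactly once.
    """
    path = Path(path)
    reads: list[SmallRNARead] = []
    seen: set[str] = set()
    for rec in read_sequences(path, "fasta"):
        head, _, suffix = rec.id.rpartition("_")
        if not head or not suffix.isdigit():
            raise FormatError(
                f"{path}: header {rec.id!r} does not end in '_<positive integer>'"
            )
        count = int(suffix)
        if count < 1:
            raise FormatError(f"{path}: header {rec.id!r}: count must be >= 1")
        if rec.seq in seen:
            raise ValidationError(f"{path}: duplicate sequence {rec.seq!r}")
        seen.add(rec.seq)
        reads.append(SmallRNARead(rec.seq, count))
    return reads


def write_collapsed_fasta(
    reads: Iterable[SmallRNARead], path: str | Path, prefix: str = "sr"
) -> None:
    with open(path, "w") as fh:
        for i, read in enumerate(reads, 1):
            fh.write(f">{prefix}{i}_{read.count}\n{read.seq}\n")


def write_table(
    rows: Sequence[Mapping[str, object]],
    path: str | Path,
    columns: Sequence[str] | None = None,
) -> None:
    """Write tab-separated UTF-8 with a header row.

    Column order is the order of ``columns`` if given, otherwise the key
    order of the first row; all rows must share the same schema.
    """
    if columns is None:
        if not rows:
            raise ValueError("columns required when writing an empty table")
        columns = list(rows[0].keys())
    for row in rows:
        if set(row.keys()) != set(columns):
            raise ValidationError("rows do not share a single column schema")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=list(columns), delimiter="\t", lineterminator="\n"
        )
        writer.writeheader()
        for row in rows:
            writer.writerow({k: row[k] for k in columns})


def read_table(path: str | Path) -> list[dict[str, str]]:
    """Read a TSV written by :func:`write_table`; all cells as strings."""
    with open(path, newline="", encoding="utf-8") as fh:
        return [dict(row) for row in csv.DictReader(fh, delimiter="\t")]
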