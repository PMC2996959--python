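"""Conserved miRNA identification by perfect match to a known mature set.

A library read is a conserved miRNA only when it is identical, full length,
to a known mature sequence (an optional 3' trimming allowance admits reads
shorter by up to N nt at the 3' end, default 0).  Matches are grouped into
families by the numeric miR token of the mature name (ath-miR156a ->
miR156), and family abundance is profiled from redundant read counts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import ValidationError
from .io import SequenceRecord, SmallRNARead, normalize_rna

_FAMILY_RE = re.compile(r"miR[a-z]*?(\d+)", re.IGNORECASE)


@dataclass(frozen=True)
class KnownMature:
    """A known mature miRNA (miRBase-style name and RNA sequence)."""

    name: str
    seq: str

    @property
    def family(self) -> str:
        return assign_family(self.name)


@dataclass(frozen=True)
class FamilyProfile:
    family: str
    member_count: int
    redundant_reads: int
    fraction_of_conserved: float


def known_from_records(records: Iterable[SequenceRecord]) -> list[KnownMature]:
    return [KnownMature(rec.id, rec.seq) for rec in records]


def assign_family(name: str) -> str:
    """Family token of a mature miRNA name: ``miR`` plus the leading integer.

    Species prefixes and letter/variant suffixes are stripped:
    ath-miR156a -> miR156, ptc-miR172b-5p -> miR172.
    """
    m = _FAMILY_RE.search(name)
    if not m:
        raise ValidationError(f"no miR<number> token in name {name!r}")
    return f"miR{int(m.group(1))}"


def match_known(
    reads: Sequence[SmallRNARead],
    known: Sequence[KnownMature],
    allow_3p_trim: int = 0,
) -> list[tuple[SmallRNARead, KnownMature]]:
    """Pairs (read, known) where the read perfectly matches the mature.

    With ``allow_3p_trim`` N > 0, a read equal to a known mature truncated
    by at most N nt at its 3' end also matches.  A read matching several
    known entries yields one pair per entry.  Output order follows the read
    list, then the known list, so it is invariant to permuting either input
    up to that canonical order.
    """
    if not known:
        raise ValidationError("known mature set is empty")
    by_seq: dict[str, list[KnownMature]] = {}
    for entry in known:
        seq = normalize_rna(entry.seq)
        bucket = by_seq.setdefault(seq, [])
        if entry not in bucket:  # duplicate name+sequence entries collapse
            bucket.append(entry)
    pairs: list[tuple[SmallRNARead, KnownMature]] = []
    for read in reads:
        hits: list[KnownMature] = []
        hits.extend(by_seq.get(read.seq, []))
        for trim in range(1, allow_3p_trim + 1):
            for seq, entries in by_seq.items():
                if len(seq) - len(read.seq) == trim and seq.startswith(read.seq):
                    hits.extend(e for e in entries if e not in hits)
        pairs.extend((read, entry) for entry in hits)
    return pairs


def family_abundance(
    matches: Sequence[tuple[SmallRNARead, KnownMature]]
) -> list[FamilyProfile]:
    """Per-family member counts, redundant reads and fraction of the total.

    ``member_count`` counts distinct matched read sequences; fractions over
    all families sum to 1.  Sorted by redundant reads descending (family
    name breaks ties).
    """
    if not matches:
        raise ValidationError("no conserved matches to profile")
    members: dict[str, set[str]] = {}
    redundant: dict[str, int] = {}
    counted: set[tuple[str, str]] = set()
    for read, entry in matches:
        fam = entry.family
        members.setdefault(fam, set()).add(read.seq)
        # a read matching several same-family entries contributes its
        # redundant count to that family once
        if (read.seq, fam) not in counted:
            counted.add((read.seq, fam))
            redundant[fam] = redundant.get(fam, 0) + read.count
    total = sum(redundant.values())
    profiles = [
        FamilyProfile(
            family=fam,
            member_count=len(members[fam]),
            redundant_reads=redundant[fam],
            fraction_of_conserved=redundant[fam] / total,
        )
        for fam in members
    ]
    profiles.sort(key=lambda p: (-p.redundant_reads, p.family))
    return profiles
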