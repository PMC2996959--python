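"""Packaged reference fixtures.

Two small published data sets from trifoliate orange (*Citrus trifoliata*)
ship with the toolkit for regression testing: the ten experimentally
supported novel miRNA candidates (ctr-miRn1-10) with their star-read support
flags, and the four validated miRNA:target-site duplexes with their reported
mismatch counts.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources


@dataclass(frozen=True)
class ReferenceCandidate:
    """One published novel-miRNA candidate row."""

    id: str
    sequence: str
    precursor_accession: str
    au_percent: float
    arm: str
    lm: int
    lp: int
    reads: int
    star_supported: bool

    @property
    def five_prime_u(self) -> bool:
        return self.sequence.startswith("U")

    @property
    def star_seq(self):  # duck-typed for summarize_candidates
        return self.sequence if self.star_supported else None


@dataclass(frozen=True)
class ReferenceDuplex:
    """One published miRNA:target duplex with its reported mismatch count."""

    mirna_id: str
    mirna_seq: str
    target_id: str
    site_seq: str
    reported_mismatches: int


def _rows(name: str) -> list[dict[str, str]]:
    text = resources.files(__package__).joinpath(name).read_text(encoding="utf-8")
    return list(csv.DictReader(text.splitlines(), delimiter="\t"))


def load_reference_candidates() -> list[ReferenceCandidate]:
    return [
        ReferenceCandidate(
            id=r["id"],
            sequence=r["sequence"],
            precursor_accession=r["precursor_accession"],
            au_percent=float(r["au_percent"]),
            arm=r["arm"],
            lm=int(r["lm"]),
            lp=int(r["lp"]),
            reads=int(r["reads"]),
            star_supported=r["star"] == "Yes",
        )
        for r in _rows("novel_candidates.tsv")
    ]


def load_reference_duplexes() -> list[ReferenceDuplex]:
    return [
        ReferenceDuplex(
            mirna_id=r["mirna_id"],
            mirna_seq=r["mirna_seq"],
            target_id=r["target_id"],
            site_seq=r["site_seq"],
            reported_mismatches=int(r["reported_mismatches"]),
        )
        for r in _rows("target_duplexes.tsv")
    ]
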