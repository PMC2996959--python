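"""miRNA target prediction by ungapped antiparallel complementarity.

A miRNA-length window slides over each transcript; at each position the
miRNA is aligned antiparallel to the site (miRNA nucleotide i against site
nucleotide L+1-i) and each opposed base pair is classed as Watson-Crick
(A:U, G:C), G:U wobble, or mismatch.  Sites within the mismatch budget
(wobbles do not count as mismatches by default) are reported as hits.  With
a budget of a few mismatches over ~21 nt, exhaustive ungapped scanning is
exact and deterministic, so no heuristic aligner is involved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .errors import ValidationError
from .io import SequenceRecord, reverse_complement

WATSON_CRICK = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
WOBBLE = {("G", "U"), ("U", "G")}


@dataclass(frozen=True)
class TargetHit:
    """A miRNA-complementary site on a transcript (1-based inclusive coords)."""

    mirna_id: str
    transcript_id: str
    site_start: int
    site_end: int
    site_seq: str
    mismatches: int
    wobbles: int
    strand: str = "+"

    @property
    def watson_crick(self) -> int:
        return len(self.site_seq) - self.mismatches - self.wobbles

    def alignment(self, mirna_seq: str) -> str:
        """Render the duplex: site 5'->3' on top, miRNA 3'->5' below.

        Watson-Crick pairs are drawn as vertical dashes, G:U wobbles as
        circles ("o"), mismatches as spaces.
        """
        marks = []
        L = len(mirna_seq)
        for i in range(L):
            duo = (mirna_seq[i], self.site_seq[L - 1 - i])
            marks.append("|" if duo in WATSON_CRICK else "o" if duo in WOBBLE else " ")
        return "\n".join(
            [
                f"5' {self.site_seq} 3'  {self.transcript_id}:{self.site_start}-{self.site_end}",
                f"   {''.join(reversed(marks))}",
                f"3' {mirna_seq[::-1]} 5'  {self.mirna_id}",
            ]
        )


def pair_class(a: str, b: str) -> str:
    """Class of an opposed base pair: watson_crick, wobble or mismatch."""
    if a not in "ACGU" or b not in "ACGU":
        raise ValidationError(f"invalid nucleotides ({a!r}, {b!r})")
    if (a, b) in WATSON_CRICK:
        return "watson_crick"
    if (a, b) in WOBBLE:
        return "wobble"
    return "mismatch"


def count_mismatches(mirna: str, site: str) -> tuple[int, int]:
    """(mismatches, wobbles) of the antiparallel miRNA:site duplex.

    Both sequences are given 5'->3'; miRNA position i is opposed to site
    position L+1-i.  Wobbles are tallied separately, not as mismatches.
    """
    if len(mirna) != len(site):
        raise ValidationError(
            f"length mismatch: miRNA {len(mirna)} nt vs site {len(site)} nt"
        )
    mismatches = wobbles = 0
    L = len(mirna)
    for i in range(L):
        cls = pair_class(mirna[i], site[L - 1 - i])
        if cls == "mismatch":
            mismatches += 1
        elif cls == "wobble":
            wobbles += 1
    return mismatches, wobbles


def scan_targets(
    mirna_id: str,
    mirna_seq: str,
    transcripts: Sequence[SequenceRecord],
    max_mismatch: int = 3,
    max_wobble: Optional[int] = None,
    wobble_as_half: bool = False,
    scan_reverse: bool = False,
) -> list[TargetHit]:
    """All complementary sites of one miRNA over a transcript set.

    Transcripts are scanned in their given orientation; ``scan_reverse``
    additionally scans the reverse complement (for unoriented ESTs), with
    hit coordinates reported on the given orientation and strand "-".
    ``wobble_as_half`` scores each wobble 0.5 toward the mismatch budget.
    Hits are sorted by (mismatches, transcript id, site start).
    """
    L = len(mirna_seq)
    if not 18 <= L <= 25:
        raise ValidationError(f"miRNA length {L} outside 18-25 nt")
    hits: list[TargetHit] = []
    for rec in transcripts:
        for strand, seq in (
            [("+", rec.seq)]
            + ([("-", reverse_complement(rec.seq))] if scan_reverse else [])
        ):
            n = len(seq)
            for start in range(0, n - L + 1):
                site = seq[start : start + L]
                mm, wob = count_mismatches(mirna_seq, site)
                budget = mm + 0.5 * wob if wobble_as_half else mm
                if budget > max_mismatch:
                    continue
                if max_wobble is not None and wob > max_wobble:
                    continue
                if strand == "+":
                    s1, s2 = start + 1, start + L
                else:
                    s1, s2 = n - start - L + 1, n - start
                hits.append(
                    TargetHit(
                        mirna_id=mirna_id,
                        transcript_id=rec.id,
                        site_start=s1,
                        site_end=s2,
                        site_seq=site,
                        mismatches=mm,
                        wobbles=wob,
                        strand=strand,
                    )
                )
    hits.sort(key=lambda h: (h.mismatches, h.transcript_id, h.site_start, h.strand))
    return hits
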