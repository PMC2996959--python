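"""5'-RACE clone mapping and miRNA-guided cleavage-site calling.

RLM-RACE clones are cDNA copies of the 3' cleavage fragment of a target
mRNA, so each clone's 5' end marks a candidate cleavage position.  Clones
are mapped by exact unique occurrence of their 5'-terminal anchor in the
target, clone ends are profiled within a 100-nt window centered on the
miRNA-complementary site, and the modal terminus is called.  Canonical
miRNA-guided cleavage leaves the fragment 5' end at the target nucleotide
opposing the miRNA's 10th nucleotide (counted from its 5' end).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .errors import ValidationError
from .io import SequenceRecord

DEFAULT_ANCHOR_LEN = 20
DEFAULT_WINDOW = 100
#: canonical cleavage opposes this miRNA nucleotide
CANONICAL_PAIRING_INDEX = 10
MIN_CLONES = 3
MIN_FRACTION = 0.3


@dataclass
class MappedEnds:
    """Clone 5'-terminus positions (1-based on the target) plus rejects."""

    termini: list[int]
    ambiguous: list[str]
    unmatched: list[str]


@dataclass
class CleavageProfile:
    """Per-position clone-end tallies within the window around a site."""

    target_id: str
    site_start: int
    site_end: int
    window: int
    termini: dict[int, int]
    total_clones: int

    @property
    def in_window_clones(self) -> int:
        return sum(self.termini.values())


@dataclass(frozen=True)
class CleavageCall:
    """The called cleavage position and which miRNA nucleotide it opposes."""

    modal_position: int
    mirna_pairing_index: Optional[int]
    modal_count: int
    modal_fraction: float
    validated: bool


def map_clone_ends(
    clones: Sequence[SequenceRecord],
    target: SequenceRecord,
    anchor_len: int = DEFAULT_ANCHOR_LEN,
) -> MappedEnds:
    """Map each clone's 5' anchor to its unique occurrence in the target.

    A clone maps iff its first ``anchor_len`` nt occur exactly once in the
    target; the terminus is that occurrence's 1-based start.  Clones with
    zero occurrences are unmatched; clones with several are ambiguous and
    excluded from the profile.
    """
    if len(target.seq) < anchor_len:
        raise ValidationError("target shorter than the anchor length")
    termini: list[int] = []
    ambiguous: list[str] = []
    unmatched: list[str] = []
    for clone in clones:
        anchor = clone.seq[:anchor_len]
        if len(anchor) < anchor_len:
            unmatched.append(clone.id)
            continue
        first = target.seq.find(anchor)
        if first == -1:
            unmatched.append(clone.id)
        elif target.seq.find(anchor, first + 1) != -1:
            ambiguous.append(clone.id)
        else:
            termini.append(first + 1)
    return MappedEnds(termini, ambiguous, unmatched)


def site_midpoint(site_start: int, site_end: int) -> int:
    """Window center: floor((start+end)/2) for even-length sites."""
    return (site_start + site_end) // 2


def cleavage_profile(
    termini: Sequence[int],
    site: tuple[int, int],
    window: int = DEFAULT_WINDOW,
    target_id: str = "",
) -> CleavageProfile:
    """Tally clone ends within the window centered on the site midpoint.

    The window spans window/2 nt each side of the midpoint, inclusive on
    both boundaries.
    """
    start, end = site
    if start < 1 or end < start:
        raise ValidationError(f"invalid site ({start}, {end})")
    mid = site_midpoint(start, end)
    half = window // 2
    counts = Counter(t for t in termini if mid - half <= t <= mid + half)
    return CleavageProfile(
        target_id=target_id,
        site_start=start,
        site_end=end,
        window=window,
        termini=dict(sorted(counts.items())),
        total_clones=len(termini),
    )


def pairing_index(position: int, mirna_len: int, site: tuple[int, int]) -> Optional[int]:
    """Which miRNA nucleotide (from its 5' end) opposes a target position.

    The site's 3'-most position opposes miRNA nucleotide 1 (antiparallel
    geometry).  None when the position falls outside the opposed span.
    """
    idx = site[1] - position + 1
    return idx if 1 <= idx <= mirna_len else None


def call_cleavage(
    profile: CleavageProfile,
    mirna_seq: str,
    min_clones: int = MIN_CLONES,
    min_fraction: float = MIN_FRACTION,
) -> CleavageCall:
    """Call the modal clone terminus and its miRNA pairing index.

    Ties on count are broken toward the position closest to the canonical
    10th-nucleotide coordinate, then toward the smaller coordinate.  The
    call is validated when the modal position carries at least
    ``min_clones`` clones and at least ``min_fraction`` of in-window clones.
    """
    if not profile.termini:
        raise ValidationError("empty cleavage profile: no in-window clone ends")
    site = (profile.site_start, profile.site_end)
    canonical = site[1] - (CANONICAL_PAIRING_INDEX - 1)
    modal = min(
        profile.termini,
        key=lambda p: (-profile.termini[p], abs(p - canonical), p),
    )
    count = profile.termini[modal]
    fraction = count / profile.in_window_clones
    idx = pairing_index(modal, len(mirna_seq), site)
    validated = idx is not None and count >= min_clones and fraction >= min_fraction
    return CleavageCall(
        modal_position=modal,
        mirna_pairing_index=idx,
        modal_count=count,
        modal_fraction=fraction,
        validated=validated,
    )


def profile_diagram(
    profile: CleavageProfile, mirna_seq: str, target_seq: str
) -> str:
    """Text rendering of the site duplex with clone-end arrows and fractions."""
    from .targets import TargetHit, count_mismatches

    s, e = profile.site_start, profile.site_end
    site_seq = target_seq[s - 1 : e]
    mm, wob = count_mismatches(mirna_seq, site_seq)
    hit = TargetHit("miRNA", profile.target_id, s, e, site_seq, mm, wob)
    lines = [hit.alignment(mirna_seq), ""]
    total = profile.in_window_clones
    for pos, n in sorted(profile.termini.items()):
        idx = pairing_index(pos, len(mirna_seq), (s, e))
        opp = f"opposes miRNA nt {idx}" if idx else "outside the opposed span"
        lines.append(f"  position {pos}: {n}/{total} clone ends ({opp})")
    return "\n".join(lines)
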