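"""Novel miRNA discovery from transcript (EST) sequences.

Un-annotated, non-conserved reads are mapped exactly onto transcripts; a
deterministic ladder of windows around each locus is folded; and each window
is screened with plant hairpin criteria: the read must sit wholly on one arm
of a single stem-loop, be mostly paired against its star region, and the
precursor must satisfy length, A+U content and MFEI thresholds.

Because a maximum-pairing folder pairs aggressively, a raw window around a
genuine precursor usually carries incidental stems in its flanks.  The
candidate precursor is therefore excised structurally before the criteria
are applied: starting from the terminal loop served by the mature's stem,
the stem is extended outward through single-branch parents and the enclosed
region becomes the precursor.  The single-hairpin test, length and
composition criteria all apply to that excised stem-loop unit, which is also
what published precursor lengths describe.

The star region is derived from the structure: the positions opposing the
mature, shifted to leave the canonical 2-nt 3' overhang on each duplex
strand.  A candidate is "star-supported" when a library read matches the
star region exactly (up to 1 nt of slack at each terminus).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

from .errors import ValidationError
from .fold import (
    DEFAULT_MODEL,
    EnergyModel,
    HairpinMetrics,
    SecondaryStructure,
    fold_rna,
    hairpin_metrics,
)
from .io import SequenceRecord, SmallRNARead, reverse_complement


@dataclass(frozen=True)
class CandidateCriteria:
    """Hairpin acceptance thresholds.

    The MFEI cutoff is calibrated to the built-in per-pair energy model
    (whose magnitudes exceed thermodynamic ones), not to the thermodynamic
    0.85 convention; recalibrate when plugging in an external folder.
    """

    max_unpaired_mature: int = 6
    max_duplex_mismatches: int = 6
    min_lp: int = 50
    max_lp: int = 300
    min_au: float = 20.0
    max_au: float = 80.0
    min_mfei: float = 0.5
    min_lm: int = 18
    max_lm: int = 25
    max_flank: int = 250
    flank_step: int = 20
    star_terminus_slack: int = 1
    require_star: bool = False


DEFAULT_CRITERIA = CandidateCriteria()


@dataclass
class Rejection:
    """A machine-readable rejection with the failed criterion as reason."""

    reason: str
    detail: str = ""


@dataclass
class HairpinCandidate:
    """An accepted novel-miRNA candidate anchored on a precursor hairpin.

    Coordinates are 1-based inclusive on the oriented transcript;
    ``star_region`` locates the predicted star within ``precursor_seq``
    (1-based, inclusive).
    """

    mature_seq: str
    precursor_id: str
    precursor_seq: str
    precursor_start: int
    precursor_end: int
    arm: str
    metrics: HairpinMetrics
    structure: SecondaryStructure
    read_count: int
    strand: str = "+"
    mature_offset: int = 0  # 0-based start of the mature within the precursor
    star_region: tuple[int, int] = (0, 0)
    star_seq: Optional[str] = None
    star_read_count: int = 0

    @property
    def five_prime_u(self) -> bool:
        return self.mature_seq.startswith("U")

    @property
    def star_region_seq(self) -> str:
        s, e = self.star_region
        return self.precursor_seq[s - 1 : e]


def map_to_transcripts(
    read_seq: str, transcripts: Sequence[SequenceRecord]
) -> list[tuple[str, int, str]]:
    """All exact ungapped occurrences of a read in a transcript set.

    Both the read and its reverse complement are searched; positions are
    1-based starts on the transcript's given orientation, with strand "-"
    marking reverse-complement occurrences.
    """
    if not 18 <= len(read_seq) <= 30:
        raise ValidationError(f"read length {len(read_seq)} outside 18-30 nt")
    rc = reverse_complement(read_seq)
    loci: list[tuple[str, int, str]] = []
    for rec in transcripts:
        for query, strand in ((read_seq, "+"), (rc, "-")):
            start = rec.seq.find(query)
            while start != -1:
                loci.append((rec.id, start + 1, strand))
                start = rec.seq.find(query, start + 1)
    return loci


def excise_candidate_windows(
    transcript_seq: str,
    locus: tuple[int, int],
    max_flank: int = 250,
    flank_step: int = 20,
) -> list[tuple[int, int]]:
    """Deterministic ladder of precursor windows around a mature locus.

    Flank lengths {step, 2*step, ..., max_flank} are taken independently on
    each side, clipped at the transcript ends, and deduplicated.  Every
    window contains the mature span.  Coordinates are 1-based inclusive.
    """
    start, end = locus
    n = len(transcript_seq)
    if not (1 <= start <= end <= n):
        raise ValidationError(f"locus ({start}, {end}) invalid on {n}-nt transcript")
    flanks = list(range(flank_step, max_flank + 1, flank_step))
    if flanks[-1] != max_flank:
        flanks.append(max_flank)
    windows = {
        (max(1, start - f5), min(n, end + f3)) for f5 in flanks for f3 in flanks
    }
    return sorted(windows)


def _parents_and_children(
    pairs: list[tuple[int, int]]
) -> tuple[dict[tuple[int, int], Optional[tuple[int, int]]], dict]:
    """Nesting tree of a nested pair list: parent and children maps."""
    parent: dict[tuple[int, int], Optional[tuple[int, int]]] = {}
    children: dict[Optional[tuple[int, int]], list[tuple[int, int]]] = {None: []}
    stack: list[tuple[int, int]] = []
    for pair in sorted(pairs):
        while stack and stack[-1][1] < pair[0]:
            stack.pop()
        par = stack[-1] if stack else None
        parent[pair] = par
        children.setdefault(par, []).append(pair)
        children.setdefault(pair, [])
        stack.append(pair)
    return parent, children


def _helix_pairs(pairs, table, mature_lo, mature_hi):
    """Pairs involving mature positions, innermost first."""
    out = []
    for p in range(mature_lo, mature_hi + 1):
        q = table[p]
        if q is not None:
            out.append((min(p, q), max(p, q)))
    return sorted(set(out), key=lambda ij: ij[0])


def evaluate_candidate(
    window_seq: str,
    mature_span: tuple[int, int],
    criteria: CandidateCriteria = DEFAULT_CRITERIA,
    model: EnergyModel = DEFAULT_MODEL,
    structure: Optional[SecondaryStructure] = None,
) -> "HairpinCandidate | Rejection":
    """Screen one folded window; return a candidate or a reasoned rejection.

    ``mature_span`` is 0-based inclusive within the window.  The returned
    candidate's precursor coordinates are 0-based inclusive within the
    window (the caller rebases them onto the transcript).
    """
    lo, hi = mature_span
    lm = hi - lo + 1
    if not criteria.min_lm <= lm <= criteria.max_lm:
        return Rejection("mature_length", f"LM={lm}")
    if structure is None:
        structure = fold_rna(window_seq, model)
    table = structure.pair_table()
    pairs = structure.pairs()
    if not pairs:
        return Rejection("not_hairpin", "no base pairs in window")

    mature_pairs = _helix_pairs(pairs, table, lo, hi)
    if not mature_pairs:
        return Rejection("mature_unpaired", "no mature position is paired")
    unpaired_mature = sum(1 for p in range(lo, hi + 1) if table[p] is None)
    if unpaired_mature > criteria.max_unpaired_mature:
        return Rejection(
            "too_many_unpaired_mature", f"{unpaired_mature} unpaired mature nt"
        )

    parent, children = _parents_and_children(pairs)

    # descend from the innermost mature pair to the terminal loop it serves
    node = mature_pairs[-1]
    while children[node]:
        if len(children[node]) > 1:
            return Rejection("not_hairpin", "bifurcation inside the mature stem")
        node = children[node][0]
    terminal = node

    # extend the stem outward through single-branch parents
    outer = terminal
    while parent[outer] is not None and len(children[parent[outer]]) == 1:
        outer = parent[outer]
    ua, ub = outer

    if not (ua <= lo and hi <= ub):
        return Rejection("mature_outside_stem", "mature extends past the stem-loop")
    ta, tb = terminal
    loop_lo, loop_hi = ta + 1, tb - 1
    if lo <= loop_hi and hi >= loop_lo:
        return Rejection("mature_in_loop", "mature overlaps the terminal loop")
    arm = "5'" if hi <= ta else "3'"

    # star region: positions opposing the mature, 2-nt 3' overhang on each
    # strand.  In a clean antiparallel duplex p + partner(p) is a constant
    # register C; the modal C over all paired mature positions is used so
    # that a frayed terminus or a small bulge cannot shift the star span.
    registers = [p + table[p] for p in range(lo, hi + 1) if table[p] is not None]
    register_counts = sorted(
        ((c, registers.count(c)) for c in set(registers)),
        key=lambda cn: (-cn[1], cn[0]),
    )
    C = register_counts[0][0]
    star_lo, star_hi = C - hi + 2, C - lo + 2
    if star_hi > len(window_seq) - 1:
        return Rejection("star_out_of_window", "star region clipped by the window")
    duplex_mismatches = sum(
        1 for q in range(star_lo, star_hi - 1) if table[q] is None
    )  # the 2 nt at the star's 3' end are the overhang, never counted
    if duplex_mismatches > criteria.max_duplex_mismatches:
        return Rejection(
            "duplex_mismatches", f"{duplex_mismatches} unpaired star-region nt"
        )

    lp = ub - ua + 1
    if not criteria.min_lp <= lp <= criteria.max_lp:
        return Rejection("lp_out_of_range", f"LP={lp}")

    precursor_seq = window_seq[ua : ub + 1]
    unit_pairs = [(i, j) for i, j in pairs if ua <= i and j <= ub]
    energy = sum(model.energy(window_seq[i], window_seq[j]) for i, j in unit_pairs)
    db = ["."] * lp
    for i, j in unit_pairs:
        db[i - ua], db[j - ua] = "(", ")"
    unit = SecondaryStructure(precursor_seq, "".join(db), energy)
    metrics = hairpin_metrics(unit)
    if not criteria.min_au <= metrics.au_percent <= criteria.max_au:
        return Rejection("au_out_of_range", f"A+U%={metrics.au_percent:.1f}")
    if metrics.mfei is None or metrics.mfei < criteria.min_mfei:
        return Rejection("mfei_low", f"MFEI={metrics.mfei}")

    star_in_unit = (star_lo - ua + 1, star_hi - ua + 1)
    if star_in_unit[0] < 1 or star_in_unit[1] > lp:
        return Rejection("star_out_of_window", "star region extends past the stem")
    return HairpinCandidate(
        mature_seq=window_seq[lo : hi + 1],
        precursor_id="",
        precursor_seq=precursor_seq,
        precursor_start=ua,
        precursor_end=ub,
        arm=arm,
        metrics=metrics,
        structure=unit,
        read_count=0,
        mature_offset=lo - ua,
        star_region=star_in_unit,
    )


def find_star(
    candidate: HairpinCandidate,
    read_counts: Mapping[str, int],
    terminus_slack: int = 1,
) -> Optional[tuple[str, int]]:
    """Look up the candidate's star sequence in the read library.

    A read equal to the structural star region matches exactly; up to
    ``terminus_slack`` nt of slack is allowed independently at each star
    terminus, preferring the smallest total shift.  Returns (sequence,
    redundant count) or None; the candidate is reported either way.
    """
    s, e = candidate.star_region
    prec = candidate.precursor_seq
    shifts = sorted(
        (
            (abs(d5) + abs(d3), d5, d3)
            for d5 in range(-terminus_slack, terminus_slack + 1)
            for d3 in range(-terminus_slack, terminus_slack + 1)
        ),
    )
    for _, d5, d3 in shifts:
        lo, hi = s + d5, e + d3
        if lo < 1 or hi > len(prec) or hi <= lo:
            continue
        star = prec[lo - 1 : hi]
        if star in read_counts:
            return star, read_counts[star]
    return None


def _best_candidate_for_locus(
    oriented_seq: str,
    locus_start: int,
    read: SmallRNARead,
    criteria: CandidateCriteria,
    model: EnergyModel,
    fold_cache: dict[str, SecondaryStructure],
) -> Optional[HairpinCandidate]:
    """Evaluate the window ladder at one locus; keep the highest-MFEI accept."""
    lm = len(read.seq)
    locus = (locus_start, locus_start + lm - 1)
    windows = excise_candidate_windows(
        oriented_seq, locus, criteria.max_flank, criteria.flank_step
    )
    best: Optional[HairpinCandidate] = None
    for ws, we in windows:
        window_seq = oriented_seq[ws - 1 : we]
        structure = fold_cache.get(window_seq)
        if structure is None:
            structure = fold_rna(window_seq, model)
            fold_cache[window_seq] = structure
        span0 = (locus[0] - ws, locus[1] - ws)
        result = evaluate_candidate(window_seq, span0, criteria, model, structure)
        if isinstance(result, Rejection):
            continue
        if best is None or (result.metrics.mfei or 0) > (best.metrics.mfei or 0):
            # rebase precursor coordinates onto the oriented transcript
            result = replace(
                result,
                precursor_start=ws + result.precursor_start,
                precursor_end=ws + result.precursor_end,
                read_count=read.count,
            )
            best = result
    return best


def discover_novel(
    reads: Sequence[SmallRNARead],
    transcripts: Sequence[SequenceRecord],
    known_seqs: Iterable[str],
    criteria: CandidateCriteria = DEFAULT_CRITERIA,
    model: EnergyModel = DEFAULT_MODEL,
) -> list[HairpinCandidate]:
    """End-to-end novel-candidate discovery.

    Reads matching the known mature set are excluded (conserved-first
    triage); candidates are deduplicated by mature sequence; candidates
    whose precursor stems overlap on the same oriented transcript are
    collapsed to the more abundant strand of the duplex (the mature), which
    resolves star reads discovered as candidates in their own right.
    Output is sorted by read count descending, mature sequence breaking ties.
    """
    known = set(known_seqs)
    read_counts = {r.seq: r.count for r in reads}
    by_id = {t.id: t for t in transcripts}
    fold_cache: dict[str, SecondaryStructure] = {}
    candidates: dict[str, HairpinCandidate] = {}

    def rank(c: HairpinCandidate) -> tuple:
        # among loci explaining the same read: star evidence first, then
        # hairpin quality, then the given orientation; deterministic overall
        return (
            c.star_seq is not None,
            c.metrics.mfei or 0.0,
            c.strand == "+",
            c.precursor_id,
            -c.precursor_start,
        )

    for read in reads:
        if read.seq in known:
            continue
        if not criteria.min_lm <= len(read.seq) <= criteria.max_lm:
            continue
        for tid, start, strand in map_to_transcripts(read.seq, transcripts):
            rec = by_id[tid]
            if strand == "+":
                oriented = rec.seq
                ostart = start
            else:
                oriented = reverse_complement(rec.seq)
                ostart = len(rec.seq) - (start + len(read.seq) - 1) + 1
            cand = _best_candidate_for_locus(
                oriented, ostart, read, criteria, model, fold_cache
            )
            if cand is None:
                continue
            # precursor span is reported on the transcript's given
            # orientation so duplex partners collide across strands
            if strand == "-":
                n = len(rec.seq)
                ps = n - cand.precursor_end + 1
                pe = n - cand.precursor_start + 1
                cand = replace(cand, precursor_start=ps, precursor_end=pe)
            cand = replace(cand, precursor_id=tid, strand=strand)
            star = find_star(cand, read_counts, criteria.star_terminus_slack)
            if star is not None:
                cand.star_seq, cand.star_read_count = star
            prev = candidates.get(read.seq)
            if prev is None or rank(cand) > rank(prev):
                candidates[read.seq] = cand

    out = [
        c
        for c in candidates.values()
        if not (criteria.require_star and c.star_seq is None)
    ]
    out = _collapse_duplex_partners(out)
    out.sort(key=lambda c: (-c.read_count, c.mature_seq))
    return out


def _collapse_duplex_partners(
    candidates: list[HairpinCandidate],
) -> list[HairpinCandidate]:
    """Keep one candidate per hairpin duplex: drop the less abundant partner.

    Two candidates are duplex partners when their precursor stems overlap on
    the same transcript, in either orientation (a mature and its star excise
    the same stem-loop).  Ties go to the lexicographically smaller mature.
    """
    order = sorted(candidates, key=lambda c: (-c.read_count, c.mature_seq))
    kept: list[HairpinCandidate] = []
    for cand in order:
        clash = any(
            k.precursor_id == cand.precursor_id
            and not (
                cand.precursor_end < k.precursor_start
                or k.precursor_end < cand.precursor_start
            )
            for k in kept
        )
        if not clash:
            kept.append(cand)
    return kept
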