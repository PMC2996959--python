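"""Synthetic small-RNA study generator with a ground-truth ledger.

Emulates the structure of a deep-sequenced plant small-RNA library: planted
conserved miRNA reads drawn from a known mature registry, novel stem-loop
precursors embedded in EST-like transcripts (with star reads emitted for a
configurable fraction of them), ncRNA fragment reads cut from per-class
reference sequences, polyA artifacts, random decoy reads, and a heavy-tailed
(Zipf) redundant-count distribution in which most unique reads are seen only
a few times.  Read lengths follow a bimodal 18-30 nt distribution with modes
at 21 and 24 nt, the canonical shape of plant libraries (21-nt miRNAs,
24-nt heterochromatic siRNAs).  5'-RACE clone sets are generated with a
dominant 5' terminus at the position opposing the miRNA's 10th nucleotide.

Every emitted record is logged in a :class:`GroundTruth` ledger so that
recovery by the analysis modules can be scored exactly.  Identical
configuration and seed give byte-identical output files.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError
from .io import (
    SequenceRecord,
    SmallRNARead,
    reverse_complement,
    write_collapsed_fasta,
    write_sequences,
)

NUCS = np.array(list("ACGU"))

#: default read-length weights over 18..30 nt (modes at 21 and 24)
DEFAULT_LENGTH_WEIGHTS: dict[int, float] = {
    18: 0.02,
    19: 0.03,
    20: 0.06,
    21: 0.20,
    22: 0.08,
    23: 0.08,
    24: 0.35,
    25: 0.06,
    26: 0.04,
    27: 0.03,
    28: 0.02,
    29: 0.015,
    30: 0.015,
}

#: miR family numbers used for the synthetic known-mature registry
_FAMILY_POOL = [
    156, 159, 160, 162, 164, 166, 167, 168, 169, 171, 172, 319, 390, 394,
    395, 396, 397, 398, 403, 408, 530, 950, 1027, 1044, 1426, 1446,
]


@dataclass
class SimConfig:
    """Study conditions for the synthetic library.

    Defaults emulate a desk-scale version of a deep-sequenced plant
    library: 20 planted conserved miRNAs, 10 planted novel precursors with
    star support emitted for about half (star_emission_prob 0.5), ncRNA
    fragment classes, polyA artifacts and 5,000 random decoys, with
    Zipf-distributed redundancy (exponent 1.2).
    """

    seed: int = 42
    n_conserved: int = 20
    n_novel: int = 10
    n_decoy_reads: int = 5000
    ncrna_reads: dict[str, int] = field(
        default_factory=lambda: {
            "rRNA": 300,
            "tRNA": 150,
            "snRNA": 60,
            "snoRNA": 40,
            "exon": 30,
            "intron": 20,
            "repeat": 20,
        }
    )
    n_polya: int = 25
    zipf_exponent: float = 1.2
    length_weights: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_WEIGHTS)
    )
    noise_fraction: float = 0.2
    star_emission_prob: float = 0.5
    n_known: int = 30
    n_transcripts: int = 40
    transcript_len: int = 220
    mature_len: int = 21
    loop_len: int = 6
    precursor_flank: int = 15
    stem_mismatches: int = 0
    max_count: int = 2000

    def __post_init__(self) -> None:
        counts = [
            self.n_conserved, self.n_novel, self.n_decoy_reads, self.n_polya,
            self.n_known, self.n_transcripts,
        ] + list(self.ncrna_reads.values())
        if any(c < 0 for c in counts):
            raise ValidationError("all generator counts must be >= 0")
        for p in (self.noise_fraction, self.star_emission_prob):
            if not 0.0 <= p <= 1.0:
                raise ValidationError("probabilities must lie in [0, 1]")


@dataclass
class PlantedPrecursor:
    mature: str
    star: str
    star_emitted: bool
    star_count: int
    mature_count: int
    transcript_id: str
    precursor_start: int  # 1-based on the transcript
    precursor_end: int
    mature_start: int
    mature_end: int
    arm: str


@dataclass
class GroundTruth:
    """The generator's ledger: what was planted, where, and how often."""

    read_truth: dict[str, dict] = field(default_factory=dict)
    conserved: list[dict] = field(default_factory=list)
    novel: list[PlantedPrecursor] = field(default_factory=list)
    race: Optional[dict] = None

    def annotation_of(self, seq: str) -> str:
        return self.read_truth[seq]["annotation"]

    def to_json(self) -> str:
        doc = {
            "read_truth": self.read_truth,
            "conserved": self.conserved,
            "novel": [asdict(p) for p in self.novel],
            "race": self.race,
        }
        return json.dumps(doc, indent=1, sort_keys=True)


@dataclass
class SyntheticLibrary:
    """In-memory bundle of every pipeline input plus the ledger."""

    reads: list[SmallRNARead]
    references: dict[str, list[SequenceRecord]]
    known: list[SequenceRecord]
    transcripts: list[SequenceRecord]
    truth: GroundTruth
    config: SimConfig

    def write_files(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        paths["reads"] = outdir / "reads_collapsed.fa"
        write_collapsed_fasta(self.reads, paths["reads"])
        for label, refs in self.references.items():
            p = outdir / f"ref_{label}.fa"
            write_sequences(refs, p)
            paths[f"ref_{label}"] = p
        paths["known"] = outdir / "known_mature.fa"
        write_sequences(self.known, paths["known"])
        paths["transcripts"] = outdir / "transcripts.fa"
        write_sequences(self.transcripts, paths["transcripts"])
        paths["truth"] = outdir / "ground_truth.json"
        paths["truth"].write_text(self.truth.to_json())
        return paths


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(NUCS, size=length))


def _draw_count(rng: np.random.Generator, exponent: float, cap: int) -> int:
    """Heavy-tailed redundant count: rank-frequency Zipf with the given
    exponent (count of the rank-r read scales as r**-exponent), drawn by
    inverting P(X >= x) = x**(-1/exponent).  Most unique reads land at a
    count of 1-2, a few reach the cap."""
    u = 1.0 - rng.random()  # (0, 1]
    return int(min(math.floor(u ** -exponent), cap))


def _draw_length(rng: np.random.Generator, weights: dict[int, float]) -> int:
    lengths = sorted(weights)
    probs = np.array([weights[L] for L in lengths], dtype=float)
    probs /= probs.sum()
    return int(rng.choice(lengths, p=probs))


def make_hairpin_precursor(
    mature: str,
    arm: str,
    loop_len: int,
    stem_mismatches: int,
    flank_len: int,
    rng: np.random.Generator,
) -> tuple[str, dict]:
    """Construct a stem-loop precursor around a mature sequence.

    Layout for a 5'-arm mature is ``flank5 + mature + loop + star_arm +
    flank3`` (mirrored for a 3'-arm mature); the star arm is the reverse
    complement of the mature with ``stem_mismatches`` substitutions at
    non-terminal positions.  The two flanks are complementary so they extend
    the stem, and the loop is drawn over {A, C} so it cannot base-pair
    internally.  Spans (1-based on the precursor) are returned for the
    ledger, including the star span shifted for the canonical 2-nt 3'
    overhang on each duplex strand.
    """
    L = len(mature)
    if not 18 <= L <= 25:
        raise ValidationError(f"mature length {L} outside 18-25 nt")
    if loop_len < 4:
        raise ValidationError("loop_len must be >= 4")
    if stem_mismatches > max(0, L - 4):
        raise ValidationError("too many stem mismatches for the mature length")
    if arm not in ("5'", "3'"):
        raise ValidationError(f"arm must be 5' or 3', got {arm!r}")

    star_arm = list(reverse_complement(mature))
    if stem_mismatches:
        positions = rng.choice(
            np.arange(2, L - 2), size=stem_mismatches, replace=False
        )
        for p in positions:
            current = star_arm[p]
            choices = [c for c in "ACGU" if c != current]
            star_arm[p] = choices[int(rng.integers(len(choices)))]
    star_arm_seq = "".join(star_arm)
    loop = "".join(rng.choice(np.array(list("AC")), size=loop_len))
    flank5 = _random_seq(rng, flank_len)
    flank3 = reverse_complement(flank5)

    if arm == "5'":
        precursor = flank5 + mature + loop + star_arm_seq + flank3
        m1 = flank_len + 1
        m2 = flank_len + L
        s1 = flank_len + L + loop_len + 1
        s2 = s1 + L - 1
    else:
        precursor = flank5 + star_arm_seq + loop + mature + flank3
        s1 = flank_len + 1
        s2 = flank_len + L
        m1 = flank_len + L + loop_len + 1
        m2 = m1 + L - 1
    # star read span: the arm shifted by +2 (2-nt 3' overhang geometry)
    star_span = (s1 + 2, s2 + 2)
    spans = {
        "mature": (m1, m2),
        "star_arm": (s1, s2),
        "star_read": star_span,
        "star_read_seq": precursor[star_span[0] - 1 : star_span[1]],
        "arm": arm,
    }
    return precursor, spans


def simulate_library(config: SimConfig) -> SyntheticLibrary:
    """Generate the full input bundle for one synthetic study."""
    rng = np.random.default_rng(config.seed)
    truth = GroundTruth()
    read_counts: dict[str, int] = {}
    forbidden: set[str] = set()

    def register(seq: str, count: int, klass: str, annotation: str, **extra) -> bool:
        if seq in read_counts:
            return False
        read_counts[seq] = count
        truth.read_truth[seq] = {"class": klass, "annotation": annotation, **extra}
        return True

    # -- known mature registry and conserved plants ------------------------
    known: list[SequenceRecord] = []
    known_seqs: set[str] = set()
    letters = "abcdefgh"
    fam_counts: dict[int, int] = {}
    while len(known) < config.n_known:
        fam = int(rng.choice(_FAMILY_POOL))
        idx = fam_counts.get(fam, 0)
        if idx >= len(letters):
            continue
        fam_counts[fam] = idx + 1
        length = int(rng.choice([20, 21, 22]))
        seq = _random_seq(rng, length)
        if seq in known_seqs:
            continue
        known_seqs.add(seq)
        known.append(SequenceRecord(f"sim-miR{fam}{letters[idx]}", seq))
    forbidden |= known_seqs

    order = rng.permutation(len(known))
    for i in order[: config.n_conserved]:
        rec = known[int(i)]
        count = 5 + _draw_count(rng, config.zipf_exponent, config.max_count)
        register(rec.seq, count, "known_miRNA", "unannotated", name=rec.id)
        truth.conserved.append({"name": rec.id, "seq": rec.seq, "count": count})

    # -- transcripts with planted novel precursors -------------------------
    transcripts: list[SequenceRecord] = []
    prec_len = 2 * config.mature_len + config.loop_len + 2 * config.precursor_flank
    host_ids = rng.permutation(config.n_transcripts)[: config.n_novel]
    planted: dict[int, tuple[str, dict]] = {}
    for j in range(config.n_novel):
        while True:
            mature = _random_seq(rng, config.mature_len)
            if mature not in forbidden and "AAAAAAAAAA" not in mature:
                break
        arm = "5'" if j % 2 == 0 else "3'"
        precursor, spans = make_hairpin_precursor(
            mature,
            arm,
            config.loop_len,
            config.stem_mismatches,
            config.precursor_flank,
            rng,
        )
        planted[int(host_ids[j])] = (precursor, spans)
        forbidden.add(mature)

    margin = 20
    for t in range(config.n_transcripts):
        if t in planted:
            precursor, spans = planted[t]
            pos = int(
                rng.integers(margin, config.transcript_len - prec_len - margin + 1)
            )
            seq = (
                _random_seq(rng, pos)
                + precursor
                + _random_seq(rng, config.transcript_len - pos - prec_len)
            )
            spans["transcript_pos"] = pos  # 0-based precursor start
        else:
            seq = _random_seq(rng, config.transcript_len)
        transcripts.append(SequenceRecord(f"est{t + 1}", seq))

    for t, (precursor, spans) in sorted(planted.items()):
        tid = f"est{t + 1}"
        pos = spans["transcript_pos"]
        mature_seq = precursor[spans["mature"][0] - 1 : spans["mature"][1]]
        star_seq = spans["star_read_seq"]
        mature_count = 5 + _draw_count(rng, config.zipf_exponent, config.max_count)
        star_emitted = bool(rng.random() < config.star_emission_prob)
        star_count = int(rng.integers(1, 4)) if star_emitted else 0
        register(
            mature_seq, mature_count, "novel_mature", "unannotated", transcript=tid
        )
        if star_emitted:
            star_emitted = register(
                star_seq, star_count, "novel_star", "unannotated", transcript=tid
            )
            if not star_emitted:
                star_count = 0
        truth.novel.append(
            PlantedPrecursor(
                mature=mature_seq,
                star=star_seq,
                star_emitted=star_emitted,
                star_count=star_count,
                mature_count=mature_count,
                transcript_id=tid,
                precursor_start=pos + 1,
                precursor_end=pos + len(precursor),
                mature_start=pos + spans["mature"][0],
                mature_end=pos + spans["mature"][1],
                arm=spans["arm"],
            )
        )

    # -- ncRNA references and fragment reads -------------------------------
    references: dict[str, list[SequenceRecord]] = {}
    ref_concat_parts: list[str] = []
    for label in sorted(config.ncrna_reads):
        refs = [
            SequenceRecord(f"{label}_ref{k + 1}", _random_seq(rng, 500))
            for k in range(2)
        ]
        references[label] = refs
        ref_concat_parts.extend(r.seq for r in refs)
    ref_concat = "#".join(ref_concat_parts)

    for label in sorted(config.ncrna_reads):
        refs = references[label]
        emitted = 0
        while emitted < config.ncrna_reads[label]:
            ref = refs[int(rng.integers(len(refs)))]
            L = _draw_length(rng, config.length_weights)
            start = int(rng.integers(0, len(ref.seq) - L + 1))
            frag = ref.seq[start : start + L]
            if frag in forbidden:
                continue
            count = _draw_count(rng, config.zipf_exponent, config.max_count)
            if register(frag, count, label, label, reference=ref.id):
                emitted += 1

    # -- polyA artifacts ----------------------------------------------------
    emitted = 0
    while emitted < config.n_polya:
        L = _draw_length(rng, config.length_weights)
        if rng.random() < 0.5:
            n_a = math.ceil(0.9 * L)
            positions = rng.permutation(L)
            chars = ["A"] * L
            for p in positions[n_a:]:
                chars[p] = str(rng.choice(np.array(list("CGU"))))
            seq = "".join(chars)
        else:
            head = _random_seq(rng, max(1, L - 10))
            seq = head + "A" * 10
        count = _draw_count(rng, config.zipf_exponent, config.max_count)
        if register(seq, count, "polyA_artifact", "polyA_artifact"):
            emitted += 1

    # -- decoys -------------------------------------------------------------
    emitted = 0
    while emitted < config.n_decoy_reads:
        L = _draw_length(rng, config.length_weights)
        seq = _random_seq(rng, L)
        if seq in forbidden or seq in ref_concat:
            continue
        if seq.count("A") / L >= 0.9 or seq.endswith("A" * 10):
            continue
        count = _draw_count(rng, config.zipf_exponent, config.max_count)
        if register(seq, count, "decoy", "unannotated"):
            emitted += 1

    reads = [SmallRNARead(seq, n) for seq, n in read_counts.items()]
    reads.sort(key=lambda r: (-r.count, r.seq))
    return SyntheticLibrary(
        reads=reads,
        references=references,
        known=known,
        transcripts=transcripts,
        truth=truth,
        config=config,
    )


def simulate_race_clones(
    target: SequenceRecord,
    site: tuple[int, int],
    mirna: str,
    n_clones: int = 15,
    noise_fraction: float = 0.2,
    seed: int = 7,
    min_clone_len: int = 30,
) -> tuple[list[SequenceRecord], dict]:
    """Generate 5'-RACE clones with a planted canonical cleavage mode.

    ceil((1 - noise_fraction) * n_clones) clone 5' ends are placed at the
    target coordinate opposing the miRNA's 10th nucleotide; the remainder
    fall uniformly within the 100-nt window around the site midpoint.  Each
    clone is the target suffix starting at its terminus.
    """
    if not 0.0 <= noise_fraction <= 1.0:
        raise ValidationError("noise_fraction must lie in [0, 1]")
    start, end = site
    n = len(target.seq)
    if not (1 <= start <= end <= n):
        raise ValidationError(f"site ({start}, {end}) invalid on {n}-nt target")
    rng = np.random.default_rng(seed)
    canonical = end - 9  # opposes miRNA nucleotide 10
    n_canonical = math.ceil((1.0 - noise_fraction) * n_clones)
    mid = (start + end) // 2
    lo = max(1, mid - 50)
    hi = min(n - min_clone_len + 1, mid + 50)
    termini = [canonical] * n_canonical + [
        int(rng.integers(lo, hi + 1)) for _ in range(n_clones - n_canonical)
    ]
    clones = [
        SequenceRecord(f"clone{i + 1}", target.seq[t - 1 :])
        for i, t in enumerate(termini)
    ]
    truth = {
        "cleavage_position": canonical,
        "pairing_index": 10,
        "termini": termini,
    }
    return clones, truth


def simulate_race_case(
    seed: int,
    mirna: Optional[str] = None,
    target_len: int = 300,
    n_clones: int = 15,
    noise_fraction: float = 0.2,
) -> tuple[SequenceRecord, tuple[int, int], str, list[SequenceRecord], dict]:
    """A complete RACE scenario: target with one planted complementary site.

    Returns (target, site, mirna, clones, truth).  The miRNA (random 21-mer
    unless given) has its exact reverse complement implanted mid-target.
    """
    rng = np.random.default_rng(seed)
    if mirna is None:
        mirna = _random_seq(rng, 21)
    site_seq = reverse_complement(mirna)
    L = len(site_seq)
    pos = target_len // 2 - L // 2  # 0-based
    seq = _random_seq(rng, target_len)
    seq = seq[:pos] + site_seq + seq[pos + L :]
    target = SequenceRecord("target1", seq)
    site = (pos + 1, pos + L)
    clones, truth = simulate_race_clones(
        target, site, mirna, n_clones, noise_fraction, seed=seed
    )
    return target, site, mirna, clones, truth
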