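"""Pipeline orchestration, configuration and paper-style reports.

``run_pipeline`` chains preprocess -> annotate -> conserved -> discover ->
targets on declared input files, logging record counts at every stage
boundary and writing one TSV per stage plus a resolved copy of the
configuration next to the outputs (full provenance).  Outputs are
deterministic given config + inputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from . import annotate as ann
from . import conserved as cons
from . import novel as nov
from . import preprocess as pre
from . import targets as tgt
from .errors import ConfigError, PipelineError
from .io import (
    SequenceRecord,
    SmallRNARead,
    read_collapsed_fasta,
    read_sequences,
    write_collapsed_fasta,
    write_table,
)

logger = logging.getLogger("srnakit")


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline plus the input/output paths.

    Unknown keys in a config document are rejected so that typos cannot
    silently fall back to defaults.
    """

    reads: Optional[str] = None  # collapsed FASTA (">id_count" headers)
    raw_reads: Optional[str] = None  # uncollapsed FASTA/FASTQ
    ncrna_refs: dict[str, str] = field(default_factory=dict)
    known: Optional[str] = None
    transcripts: Optional[str] = None
    out: str = "srnakit_out"
    seed: int = 42
    min_len: int = 18
    max_len: int = 30
    priority: list[str] = field(default_factory=lambda: list(ann.DEFAULT_PRIORITY))
    polya_fraction: float = ann.POLYA_FRACTION
    polya_tail_run: int = ann.POLYA_TAIL_RUN
    allow_3p_trim: int = 0
    criteria: nov.CandidateCriteria = field(default_factory=nov.CandidateCriteria)
    max_mismatch: int = 3
    scan_reverse: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        doc = dict(doc)
        known_fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known_fields
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "criteria" in doc and isinstance(doc["criteria"], dict):
            crit_fields = {f.name for f in dataclasses.fields(nov.CandidateCriteria)}
            bad = set(doc["criteria"]) - crit_fields
            if bad:
                raise ConfigError(f"unknown criteria keys: {sorted(bad)}")
            doc["criteria"] = nov.CandidateCriteria(**doc["criteria"])
        return cls(**doc)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ConfigError(f"{path}: config document must be a mapping")
        return cls.from_dict(doc)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)


@dataclass
class CandidateSummary:
    """Headline tallies over a novel-candidate set."""

    n_candidates: int
    n_five_prime_u: int
    n_star_supported: int
    star_supported_percent: Optional[float]


def summarize_candidates(
    candidates: Sequence,  # HairpinCandidate or any object with the two attrs
) -> CandidateSummary:
    """Count 5'-U starts and star support over candidates.

    ``star_supported_percent`` is None (reported as NA) for an empty list.
    """
    n = len(candidates)
    n_u = sum(1 for c in candidates if getattr(c, "five_prime_u"))
    n_star = sum(1 for c in candidates if getattr(c, "star_seq", None))
    return CandidateSummary(
        n_candidates=n,
        n_five_prime_u=n_u,
        n_star_supported=n_star,
        star_supported_percent=(100.0 * n_star / n) if n else None,
    )


CANDIDATE_COLUMNS = [
    "id",
    "mature_seq",
    "precursor_id",
    "au_percent",
    "mfe_abs",
    "amfe",
    "mfei",
    "arm",
    "lm",
    "lp",
    "read_count",
    "star",
]


def candidate_rows(candidates: Sequence[nov.HairpinCandidate]) -> list[dict]:
    rows = []
    for i, c in enumerate(candidates, 1):
        m = c.metrics
        rows.append(
            {
                "id": f"cand{i}",
                "mature_seq": c.mature_seq,
                "precursor_id": c.precursor_id,
                "au_percent": f"{m.au_percent:.1f}",
                "mfe_abs": f"{m.mfe_abs:.1f}",
                "amfe": f"{m.amfe:.1f}",
                "mfei": f"{m.mfei:.3f}" if m.mfei is not None else "NA",
                "arm": c.arm,
                "lm": len(c.mature_seq),
                "lp": m.precursor_len,
                "read_count": c.read_count,
                "star": "Yes" if c.star_seq else "No",
            }
        )
    return rows


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the output directory.

    Raises :class:`PipelineError` naming the failing stage on any error.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    outdir = Path(config.out)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config_resolved.yaml").write_text(config.to_yaml())

    # ---- preprocess -------------------------------------------------------
    try:
        if config.raw_reads:
            raw = read_sequences(config.raw_reads)
            reads = pre.collapse_reads(raw)
        elif config.reads:
            reads = pre.collapse_counted(read_collapsed_fasta(config.reads))
        else:
            raise PipelineError("preprocess: no read input configured")
        if not reads:
            raise PipelineError("preprocess: read input is empty")
        kept, discarded = pre.filter_by_length(reads, config.min_len, config.max_len)
        if not kept:
            raise PipelineError("preprocess: no reads within the length window")
        assert len(kept) + len(discarded) == len(reads)
        dist = pre.length_distribution(kept, config.min_len, config.max_len)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"preprocess: {exc}") from exc
    logger.info("preprocess: %d unique in, %d kept, %d discarded",
                len(reads), len(kept), len(discarded))
    write_collapsed_fasta(kept, outdir / "reads_filtered.fa")
    dist.reset_index().to_csv(outdir / "length_distribution.tsv", sep="\t", index=False)

    # ---- annotate ---------------------------------------------------------
    try:
        index = ann.ReferenceIndex.from_fastas(config.ncrna_refs)
        classified = [
            (
                r,
                ann.classify_read(
                    r, index, config.priority,
                    config.polya_fraction, config.polya_tail_run,
                ),
            )
            for r in kept
        ]
        summary = ann.annotation_summary(classified)
    except Exception as exc:
        raise PipelineError(f"annotate: {exc}") from exc
    unannotated = [r for r, label in classified if label == "unannotated"]
    assert sum(1 for _ in classified) == len(kept)
    logger.info("annotate: %d reads in, %d unannotated", len(kept), len(unannotated))
    summary.reset_index().to_csv(outdir / "annotation_summary.tsv", sep="\t", index=False)
    write_table(
        [{"seq": r.seq, "count": r.count, "class": label} for r, label in classified],
        outdir / "read_classes.tsv",
        columns=["seq", "count", "class"],
    )

    # ---- conserved --------------------------------------------------------
    matches: list = []
    known_seqs: set[str] = set()
    if config.known:
        try:
            known = cons.known_from_records(read_sequences(config.known))
            matches = cons.match_known(unannotated, known, config.allow_3p_trim)
            known_seqs = {e.seq for e in known}
        except Exception as exc:
            raise PipelineError(f"conserved: {exc}") from exc
        logger.info("conserved: %d matches", len(matches))
        write_table(
            [
                {"read_seq": r.seq, "count": r.count, "known": e.name,
                 "family": e.family}
                for r, e in matches
            ],
            outdir / "conserved_matches.tsv",
            columns=["read_seq", "count", "known", "family"],
        )
        if matches:
            write_table(
                [asdict(p) for p in cons.family_abundance(matches)],
                outdir / "family_profiles.tsv",
                columns=["family", "member_count", "redundant_reads",
                         "fraction_of_conserved"],
            )

    # ---- novel discovery --------------------------------------------------
    candidates: list[nov.HairpinCandidate] = []
    if config.transcripts:
        try:
            transcripts = read_sequences(config.transcripts)
            candidates = nov.discover_novel(
                unannotated, transcripts, known_seqs, config.criteria
            )
        except Exception as exc:
            raise PipelineError(f"discover: {exc}") from exc
        logger.info("discover: %d candidates", len(candidates))
        write_table(
            candidate_rows(candidates),
            outdir / "novel_candidates.tsv",
            columns=CANDIDATE_COLUMNS,
        )
        with open(outdir / "novel_structures.txt", "w") as fh:
            for i, c in enumerate(candidates, 1):
                fh.write(f">cand{i} {c.precursor_id} arm={c.arm}\n")
                fh.write(f"{c.structure.seq}\n{c.structure.dotbracket}\n")

        # ---- targets ------------------------------------------------------
        try:
            hits = []
            for i, c in enumerate(candidates, 1):
                hits.extend(
                    tgt.scan_targets(
                        f"cand{i}", c.mature_seq, transcripts,
                        config.max_mismatch, scan_reverse=config.scan_reverse,
                    )
                )
        except Exception as exc:
            raise PipelineError(f"targets: {exc}") from exc
        logger.info("targets: %d hits", len(hits))
        write_table(
            [
                {
                    "mirna_id": h.mirna_id,
                    "transcript_id": h.transcript_id,
                    "site_start": h.site_start,
                    "site_end": h.site_end,
                    "strand": h.strand,
                    "site_seq": h.site_seq,
                    "mismatches": h.mismatches,
                    "wobbles": h.wobbles,
                }
                for h in hits
            ],
            outdir / "target_hits.tsv",
            columns=[
                "mirna_id", "transcript_id", "site_start", "site_end",
                "strand", "site_seq", "mismatches", "wobbles",
            ],
        )

    summary_doc = {
        "unique_reads": len(reads),
        "kept_reads": len(kept),
        "unannotated_reads": len(unannotated),
        "conserved_matches": len(matches),
        "candidates": asdict(summarize_candidates(candidates)),
    }
    (outdir / "summary.json").write_text(json.dumps(summary_doc, indent=1, sort_keys=True))
    return outdir
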