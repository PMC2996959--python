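import hashlib
import json
from pathlib import Path

import numpy as np
import pytest

from srnakit.errors import ValidationError
from srnakit.fold import fold_rna, is_hairpin
from srnakit.io import reverse_complement
from srnakit.synthetic import (
    SimConfig,
    make_hairpin_precursor,
    simulate_library,
    simulate_race_clones,
    simulate_race_case,
)

SMALL = dict(
    n_conserved=5, n_novel=3, n_decoy_reads=300,
    ncrna_reads={"rRNA": 40, "tRNA": 20}, n_polya=5,
)


def _hash_dir(d: Path) -> str:
    h = hashlib.sha256()
    for p in sorted(d.rglob("*")):
        if p.is_file():
            h.update(p.name.encode())
            h.update(p.read_bytes())
    return h.hexdigest()


def test_precursor_length_arithmetic():
    rng = np.random.default_rng(0)
    precursor, spans = make_hairpin_precursor("U" * 10 + "A" * 11, "5'", 6, 0, 15, rng)
    assert len(precursor) == 21 + 6 + 21 + 30  # = 78
    assert spans["mature"] == (16, 36)


def test_five_prime_arm_mature_precedes_loop():
    rng = np.random.default_rng(1)
    _, spans5 = make_hairpin_precursor("ACGU" * 5 + "A", "5'", 6, 0, 10, rng)
    _, spans3 = make_hairpin_precursor("ACGU" * 5 + "A", "3'", 6, 0, 10, rng)
    assert spans5["mature"][1] < spans5["star_arm"][0]
    assert spans3["star_arm"][1] < spans3["mature"][0]


def test_star_arm_is_reverse_complement_without_mismatches():
    rng = np.random.default_rng(2)
    mature = "UGAGGUAGUAGGUUGUAUAGU"
    precursor, spans = make_hairpin_precursor(mature, "5'", 6, 0, 15, rng)
    s1, s2 = spans["star_arm"]
    assert precursor[s1 - 1 : s2] == reverse_complement(mature)


def test_stem_mismatch_count_applied():
    rng = np.random.default_rng(3)
    mature = "UGAGGUAGUAGGUUGUAUAGU"
    precursor, spans = make_hairpin_precursor(mature, "5'", 6, 3, 15, rng)
    s1, s2 = spans["star_arm"]
    star = precursor[s1 - 1 : s2]
    diffs = sum(a != b for a, b in zip(star, reverse_complement(mature)))
    assert diffs == 3


def test_infeasible_geometry_rejected():
    rng = np.random.default_rng(4)
    with pytest.raises(ValidationError):
        make_hairpin_precursor("ACGUACGUACGUACGUACGUA", "5'", 3, 0, 15, rng)
    with pytest.raises(ValidationError):
        make_hairpin_precursor("ACGU" * 10, "5'", 6, 0, 15, rng)  # 40 nt mature


def test_generated_precursors_fold_to_ledger_arms(lib42):
    for p in lib42.truth.novel:
        rec = next(t for t in lib42.transcripts if t.id == p.transcript_id)
        precursor = rec.seq[p.precursor_start - 1 : p.precursor_end]
        structure = fold_rna(precursor)
        ok, arm_map = is_hairpin(structure)
        assert ok
        offset = p.mature_start - p.precursor_start
        labels = {arm_map[offset + k] for k in range(len(p.mature))}
        assert labels == {p.arm}


def test_ledger_covers_every_read_exactly_once(lib42):
    assert len(lib42.truth.read_truth) == len(lib42.reads)
    assert {r.seq for r in lib42.reads} == set(lib42.truth.read_truth)


def test_planted_class_counts_match_config(lib42):
    cfg = lib42.config
    by_class: dict[str, int] = {}
    for info in lib42.truth.read_truth.values():
        by_class[info["class"]] = by_class.get(info["class"], 0) + 1
    assert by_class["known_miRNA"] == cfg.n_conserved
    assert by_class["novel_mature"] == cfg.n_novel
    assert by_class["decoy"] == cfg.n_decoy_reads
    assert by_class["polyA_artifact"] == cfg.n_polya
    for label, n in cfg.ncrna_reads.items():
        assert by_class[label] == n
    emitted_stars = sum(1 for p in lib42.truth.novel if p.star_emitted)
    assert by_class.get("novel_star", 0) == emitted_stars


def test_length_histogram_modes_at_21_and_24(lib42):
    from collections import Counter

    hist = Counter(len(r) for r in lib42.reads)
    top_two = {L for L, _ in hist.most_common(2)}
    assert top_two == {21, 24}


def test_most_reads_have_low_redundancy(lib42):
    """Zipf abundance: the majority of unique reads are seen only a few times."""
    low = sum(1 for r in lib42.reads if r.count <= 2)
    assert low > len(lib42.reads) / 2


def test_simulate_byte_identical_under_fixed_seed(tmp_path):
    a, b = tmp_path / "a", tmp_path / "b"
    simulate_library(SimConfig(seed=5, **SMALL)).write_files(a)
    simulate_library(SimConfig(seed=5, **SMALL)).write_files(b)
    assert _hash_dir(a) == _hash_dir(b)


def test_different_seed_changes_output(tmp_path):
    a, b = tmp_path / "a", tmp_path / "b"
    simulate_library(SimConfig(seed=5, **SMALL)).write_files(a)
    simulate_library(SimConfig(seed=6, **SMALL)).write_files(b)
    assert _hash_dir(a) != _hash_dir(b)


def test_degenerate_config_only_planted_mirna_reads():
    cfg = SimConfig(seed=1, n_decoy_reads=0, ncrna_reads={}, n_polya=0,
                    n_conserved=2, n_novel=2)
    lib = simulate_library(cfg)
    classes = {info["class"] for info in lib.truth.read_truth.values()}
    assert classes <= {"known_miRNA", "novel_mature", "novel_star"}


def test_ground_truth_json_is_loadable(lib42, tmp_path):
    paths = simulate_library(SimConfig(seed=2, **SMALL)).write_files(tmp_path / "x")
    doc = json.loads(paths["truth"].read_text())
    assert set(doc) == {"read_truth", "conserved", "novel", "race"}


def test_race_zero_noise_all_termini_identical():
    target, site, mirna, clones, truth = simulate_race_case(3, noise_fraction=0.0)
    starts = {len(target.seq) - len(c.seq) + 1 for c in clones}
    assert starts == {truth["cleavage_position"]}


def test_race_full_noise_has_no_planted_mode():
    target, site, mirna, clones, truth = simulate_race_case(3, noise_fraction=1.0)
    canonical = truth["cleavage_position"]
    at_mode = sum(1 for t in truth["termini"] if t == canonical)
    assert at_mode <= 3  # no systematic pile-up


def test_race_invalid_noise_rejected():
    target, site, mirna, _, _ = simulate_race_case(1)
    with pytest.raises(ValidationError):
        simulate_race_clones(target, site, mirna, noise_fraction=1.5)
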