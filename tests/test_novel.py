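import random

import numpy as np
import pytest

from srnakit.errors import ValidationError
from srnakit.fold import fold_rna
from srnakit.io import SequenceRecord, SmallRNARead, reverse_complement
from srnakit.novel import (
    CandidateCriteria,
    HairpinCandidate,
    Rejection,
    discover_novel,
    evaluate_candidate,
    excise_candidate_windows,
    find_star,
    map_to_transcripts,
)
from srnakit.synthetic import SimConfig, make_hairpin_precursor, simulate_library


def _rand(rng, n):
    return "".join(rng.choice("ACGU") for _ in range(n))


# ---------------------------------------------------------------- mapping


def test_planted_read_maps_to_its_locus():
    rng = random.Random(1)
    read = _rand(rng, 21)
    est = _rand(rng, 100) + read + _rand(rng, 80)
    loci = map_to_transcripts(read, [SequenceRecord("est1", est)])
    assert loci == [("est1", 101, "+")]


def test_absent_read_maps_nowhere():
    rng = random.Random(2)
    assert map_to_transcripts(_rand(rng, 21), [SequenceRecord("e", _rand(rng, 200))]) == []


def test_reverse_complement_occurrence_reported_on_minus():
    rng = random.Random(3)
    read = _rand(rng, 21)
    est = _rand(rng, 50) + reverse_complement(read) + _rand(rng, 50)
    loci = map_to_transcripts(read, [SequenceRecord("e", est)])
    assert loci == [("e", 51, "-")]


def test_mapping_matches_generator_ledger(lib42):
    """Planted matures map to their recorded transcripts and positions."""
    for p in lib42.truth.novel:
        loci = map_to_transcripts(p.mature, lib42.transcripts)
        assert (p.transcript_id, p.mature_start, "+") in loci


# ---------------------------------------------------------------- windows


def test_window_clipping_at_transcript_start():
    windows = excise_candidate_windows("A" * 200, (10, 30), max_flank=40)
    assert all(ws >= 1 for ws, _ in windows)
    assert min(ws for ws, _ in windows) == 1  # clipped upstream flank


def test_window_ladder_combinatorics():
    windows = excise_candidate_windows("A" * 1000, (500, 520), max_flank=40)
    assert len(windows) == 4  # {20,40} x {20,40}


def test_every_window_contains_the_locus():
    rng = random.Random(4)
    seq = _rand(rng, 400)
    for _ in range(20):
        start = rng.randint(1, 380)
        end = min(400, start + 20)
        for ws, we in excise_candidate_windows(seq, (start, end)):
            assert ws <= start and end <= we


def test_invalid_locus_rejected():
    with pytest.raises(ValidationError):
        excise_candidate_windows("ACGU" * 10, (0, 5))


# ---------------------------------------------------------------- criteria


def _planted_window(seed=0, arm="5'", flank=15, loop=6, extra=0):
    rng = np.random.default_rng(seed)
    mature = _rand(random.Random(seed + 100), 21)
    precursor, spans = make_hairpin_precursor(mature, arm, loop, 0, flank, rng)
    pad5 = _rand(random.Random(seed + 200), extra)
    pad3 = _rand(random.Random(seed + 300), extra)
    window = pad5 + precursor + pad3
    m1, m2 = spans["mature"]
    span0 = (extra + m1 - 1, extra + m2 - 1)  # 0-based within the window
    return window, span0, spans, mature


def test_clean_planted_precursor_is_accepted():
    window, span0, spans, mature = _planted_window(seed=1)
    result = evaluate_candidate(window, span0)
    assert isinstance(result, HairpinCandidate)
    assert result.arm == spans["arm"]
    assert result.mature_seq == mature
    assert result.metrics.precursor_len >= 48


def test_star_region_has_two_nt_overhang_on_perfect_duplex():
    """On a perfect planted duplex the computed star matches the ledger span."""
    for seed, arm in [(2, "5'"), (3, "3'")]:
        window, span0, spans, _ = _planted_window(seed=seed, arm=arm)
        cand = evaluate_candidate(window, span0)
        assert isinstance(cand, HairpinCandidate)
        assert cand.star_region_seq == spans["star_read_seq"]


def test_mature_straddling_loop_is_rejected():
    window, span0, spans, _ = _planted_window(seed=4)
    # shift the "mature" span so it covers the terminal loop
    m1, m2 = span0
    shifted = (m1 + 15, m2 + 15)
    result = evaluate_candidate(window, shifted)
    assert isinstance(result, Rejection)
    assert result.reason in ("mature_in_loop", "not_hairpin", "mature_unpaired")


def test_random_windows_overwhelmingly_rejected():
    """Windows of random sequence fail the hairpin criteria >= 95/100 times."""
    rng = random.Random(1234)
    rejected = 0
    for _ in range(100):
        window = _rand(rng, 81)
        if isinstance(evaluate_candidate(window, (30, 50)), Rejection):
            rejected += 1
    assert rejected >= 95


def test_tightening_any_threshold_never_adds_candidates():
    """Each criterion is monotone: stricter settings accept a subset."""
    windows = [_planted_window(seed=s)[:2] for s in range(6)]
    windows += [(_rand(random.Random(50 + s), 120), (50, 70)) for s in range(6)]

    def n_accepted(criteria):
        return sum(
            isinstance(evaluate_candidate(w, span, criteria), HairpinCandidate)
            for w, span in windows
        )

    base = CandidateCriteria()
    baseline = n_accepted(base)
    tighter = [
        CandidateCriteria(max_unpaired_mature=0),
        CandidateCriteria(max_duplex_mismatches=0),
        CandidateCriteria(min_lp=80),
        CandidateCriteria(max_lp=75),
        CandidateCriteria(min_au=60.0),
        CandidateCriteria(max_au=55.0),
        CandidateCriteria(min_mfei=2.5),
        CandidateCriteria(min_lm=22),
    ]
    for crit in tighter:
        assert n_accepted(crit) <= baseline


# ---------------------------------------------------------------- find_star


def test_star_found_with_exact_read():
    window, span0, spans, _ = _planted_window(seed=5)
    cand = evaluate_candidate(window, span0)
    star_read = spans["star_read_seq"]
    found = find_star(cand, {star_read: 3})
    assert found == (star_read, 3)


def test_star_found_with_one_nt_slack():
    window, span0, spans, _ = _planted_window(seed=6)
    cand = evaluate_candidate(window, span0)
    trimmed = spans["star_read_seq"][:-1]
    assert find_star(cand, {trimmed: 2}) == (trimmed, 2)


def test_star_absent_reported_as_none():
    window, span0, spans, _ = _planted_window(seed=7)
    cand = evaluate_candidate(window, span0)
    assert find_star(cand, {"UGAGGUAGUAGGUUGUAUAGUU": 9}) is None


# ---------------------------------------------------------------- discovery


def test_reads_matching_known_set_give_no_candidates(lib42):
    matures = [SmallRNARead(p.mature, 5) for p in lib42.truth.novel]
    known = {p.mature for p in lib42.truth.novel}
    assert discover_novel(matures, lib42.transcripts, known) == []


def test_recovery_on_seed_42(lib42, cands42):
    planted = {p.mature for p in lib42.truth.novel}
    recovered = {c.mature_seq for c in cands42}
    assert recovered == planted  # precision = recall = 1


def test_arm_and_star_match_ledger_on_seed_42(lib42, cands42):
    truth = {p.mature: p for p in lib42.truth.novel}
    for c in cands42:
        p = truth[c.mature_seq]
        assert (c.star_seq is not None) == p.star_emitted
        if c.star_seq is not None:
            assert c.star_seq == p.star
            assert c.star_read_count == p.star_count
        assert c.read_count == p.mature_count
        if c.strand == "+":
            assert c.arm == p.arm


@pytest.mark.parametrize("seed", [7, 11])
def test_recovery_on_further_seeds(seed):
    """Noise-free recovery holds across independent generator seeds."""
    lib = simulate_library(SimConfig(seed=seed))
    unannotated = [
        r for r in lib.reads if lib.truth.annotation_of(r.seq) == "unannotated"
    ]
    cands = discover_novel(unannotated, lib.transcripts, {k.seq for k in lib.known})
    assert {c.mature_seq for c in cands} == {p.mature for p in lib.truth.novel}


def test_candidates_sorted_by_read_count(cands42):
    counts = [c.read_count for c in cands42]
    assert counts == sorted(counts, reverse=True)


def test_reported_arm_is_structural(cands42):
    """The arm label agrees with the mature's side of the terminal loop."""
    from srnakit.fold import is_hairpin

    for c in cands42:
        ok, arm_map = is_hairpin(c.structure)
        assert ok
        span = range(c.mature_offset, c.mature_offset + len(c.mature_seq))
        labels = {arm_map[p] for p in span}
        assert labels == {c.arm}
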