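import random
import shutil

import pytest
from hypothesis import given
from hypothesis import strategies as st

from _oracles import brute_force_mfe, enumerate_structures, structure_energy
from srnakit.errors import CapacityError, ValidationError
from srnakit.fold import (
    DEFAULT_MODEL,
    EnergyModel,
    RNAfoldFolder,
    SecondaryStructure,
    fold_rna,
    hairpin_metrics,
    is_hairpin,
)

rna = st.text(alphabet="ACGU", min_size=1, max_size=40)


def test_unpairable_sequence_is_open():
    s = fold_rna("AAAAAAA")
    assert s.dotbracket == "......."
    assert s.energy == 0.0


def test_worked_hairpin():
    s = fold_rna("GGGAAACCC")
    assert s.dotbracket == "(((...)))"
    assert s.energy == -9.0


def test_invalid_alphabet_rejected():
    with pytest.raises(ValidationError):
        fold_rna("ACGT")


def test_length_bound_enforced():
    with pytest.raises(CapacityError):
        fold_rna("A" * 1001)


def test_dp_equals_exhaustive_enumeration():
    """DP optimum equals brute-force enumeration on 100 random short seqs."""
    rng = random.Random(123)
    for _ in range(100):
        seq = "".join(rng.choice("ACGU") for _ in range(rng.randint(1, 12)))
        assert abs(fold_rna(seq).energy - brute_force_mfe(seq)) < 1e-9, seq


def test_dp_structure_is_valid_and_scores_its_own_energy():
    rng = random.Random(7)
    for _ in range(50):
        seq = "".join(rng.choice("ACGU") for _ in range(rng.randint(5, 60)))
        s = fold_rna(seq)
        pairs = frozenset(s.pairs())
        # every pair legal, min loop respected
        for i, j in pairs:
            assert (seq[i], seq[j]) in DEFAULT_MODEL.pair_energies
            assert j - i > DEFAULT_MODEL.min_loop
        assert abs(structure_energy(seq, pairs) - s.energy) < 1e-9


@given(rna)
def test_dotbracket_well_formed(seq):
    s = fold_rna(seq)
    assert len(s.dotbracket) == len(seq)
    depth = 0
    for c in s.dotbracket:
        depth += {"(": 1, ")": -1, ".": 0}[c]
        assert depth >= 0
    assert depth == 0


def test_energy_monotone_in_pair_energy_magnitude():
    """Scaling all pair energies up never raises the optimum."""
    rng = random.Random(9)
    for _ in range(20):
        seq = "".join(rng.choice("ACGU") for _ in range(30))
        base = fold_rna(seq, DEFAULT_MODEL).energy
        stronger = EnergyModel(
            {k: 2.0 * v for k, v in DEFAULT_MODEL.pair_energies.items()}
        )
        assert fold_rna(seq, stronger).energy <= base


def test_fold_is_deterministic():
    seq = "GGCAUCGAUCGGCGAUAUCGCGAUCGAUGCC"
    assert fold_rna(seq).dotbracket == fold_rna(seq).dotbracket


def test_metrics_forced_by_formulas():
    s = SecondaryStructure("GC" * 25 + "AU" * 25, "." * 100, -50.0)
    m = hairpin_metrics(s)
    assert m.amfe == 50.0
    assert m.mfei == 1.0
    assert m.au_percent == 50.0
    assert m.precursor_len == 100


def test_metrics_mfei_undefined_without_gc():
    s = SecondaryStructure("AUAUAUAU", "........", 0.0)
    m = hairpin_metrics(s)
    assert m.au_percent == 100.0
    assert m.mfei is None


def test_metrics_independent_recomputation():
    """Metrics agree with a direct one-off recomputation on folded RNA."""
    rng = random.Random(11)
    for _ in range(50):
        seq = "".join(rng.choice("ACGU") for _ in range(rng.randint(20, 80)))
        s = fold_rna(seq)
        m = hairpin_metrics(s)
        L = len(seq)
        gc = 100.0 * sum(c in "GC" for c in seq) / L
        amfe = abs(s.energy) / L * 100.0
        assert abs(m.amfe - amfe) < 1e-9
        assert abs(m.au_percent - (100.0 - gc)) < 1e-9
        if gc > 0:
            assert abs(m.mfei - amfe / gc) < 1e-9


def test_is_hairpin_simple_stem():
    ok, arms = is_hairpin(SecondaryStructure("GGGAAACCC", "(((...)))", -9.0))
    assert ok
    assert arms == ["5'"] * 3 + ["loop"] * 3 + ["3'"] * 3


def test_two_stems_are_not_a_hairpin():
    s = SecondaryStructure("GGAAAACCGGAAAACC", "((....))((....))", -12.0)
    ok, arms = is_hairpin(s)
    assert not ok and arms is None


def test_open_chain_is_not_a_hairpin():
    ok, _ = is_hairpin(SecondaryStructure("ACGU", "....", 0.0))
    assert not ok


def test_planted_precursors_fold_to_single_hairpins():
    """Generated stem-loops are single hairpins with ledger-consistent arms."""
    import numpy as np

    from srnakit.synthetic import make_hairpin_precursor

    rng = np.random.default_rng(3)
    for k in range(100):
        mature = "".join(rng.choice(list("ACGU"), size=21))
        arm = "5'" if k % 2 == 0 else "3'"
        precursor, spans = make_hairpin_precursor(mature, arm, 6, 0, 15, rng)
        s = fold_rna(precursor)
        ok, arm_map = is_hairpin(s)
        assert ok
        m1, m2 = spans["mature"]
        labels = {arm_map[p] for p in range(m1 - 1, m2)}
        assert labels == {arm}


@pytest.mark.skipif(shutil.which("RNAfold") is None, reason="RNAfold not installed")
def test_rnafold_adapter_parses_output():
    s = RNAfoldFolder().fold("GGGGGAAAACCCCC")
    assert len(s.dotbracket) == 14
    assert s.energy <= 0.0
    s.pair_table()  # balanced
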