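"""RNA secondary-structure prediction and hairpin metrics.

The built-in folder is an energy-scored Nussinov dynamic program: each base
pair contributes a fixed energy (defaults G:C -3.0, A:U -2.0, G:U -1.0
kcal/mol), hairpin loops span at least 3 unpaired nucleotides, and the
minimum-energy nested structure is returned with a fixed traceback order so
results are bit-stable across platforms.  This is deliberately simpler than
a nearest-neighbor thermodynamic model: it keeps the toolkit self-contained
and deterministic, and every hairpin-quality threshold downstream is
calibrated to it.  A thermodynamic folder (e.g. RNAfold) can be plugged in
through the same interface, in which case MFE magnitudes become comparable
to published values.

Hairpin quality uses the standard plant-miRNA indices: AMFE (|MFE| per
100 nt) and MFEI (AMFE divided by GC percentage), plus A+U content and
precursor length.
"""

from __future__ import annotations

import math
import shutil
import subprocess
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .errors import CapacityError, ValidationError
from .io import RNA_ALPHABET, au_percent, gc_percent

MAX_FOLD_LEN = 1000
_INF = 1e9

DEFAULT_PAIR_ENERGIES: dict[tuple[str, str], float] = {
    ("G", "C"): -3.0,
    ("C", "G"): -3.0,
    ("A", "U"): -2.0,
    ("U", "A"): -2.0,
    ("G", "U"): -1.0,
    ("U", "G"): -1.0,
}


@dataclass(frozen=True)
class EnergyModel:
    """Per-pair energies (kcal/mol, negative) and minimum hairpin loop size."""

    pair_energies: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_PAIR_ENERGIES)
    )
    min_loop: int = 3

    def energy(self, a: str, b: str) -> float:
        """Energy of pairing bases a:b, +inf sentinel if unpairable."""
        return self.pair_energies.get((a, b), _INF)


DEFAULT_MODEL = EnergyModel()


@dataclass
class SecondaryStructure:
    """A nested structure in dot-bracket notation with its total energy."""

    seq: str
    dotbracket: str
    energy: float

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.dotbracket):
            raise ValidationError("dotbracket length differs from sequence length")

    def pair_table(self) -> list[Optional[int]]:
        """0-based partner index per position, None where unpaired."""
        table: list[Optional[int]] = [None] * len(self.dotbracket)
        stack: list[int] = []
        for i, c in enumerate(self.dotbracket):
            if c == "(":
                stack.append(i)
            elif c == ")":
                if not stack:
                    raise ValidationError("unbalanced dot-bracket")
                j = stack.pop()
                table[i], table[j] = j, i
        if stack:
            raise ValidationError("unbalanced dot-bracket")
        return table

    def pairs(self) -> list[tuple[int, int]]:
        """Base pairs as (i, j) with i < j, sorted by i."""
        table = self.pair_table()
        return [(i, j) for i, j in enumerate(table) if j is not None and i < j]


@dataclass(frozen=True)
class HairpinMetrics:
    """Hairpin quality indices for a folded precursor.

    ``mfei`` is None when the sequence contains no G or C (the index is
    undefined at GC% = 0).
    """

    mfe_abs: float
    amfe: float
    mfei: Optional[float]
    au_percent: float
    gc_percent: float
    precursor_len: int


def fold_rna(seq: str, model: EnergyModel = DEFAULT_MODEL) -> SecondaryStructure:
    """Minimum-energy nested structure of an RNA sequence.

    Dynamic program over intervals:
        E(i,j) = min( E(i+1,j),
                      min_k e(i,k) + E(i+1,k-1) + E(k+1,j) )
    with k ranging over pairable partners of i at least min_loop+1 away.
    Traceback is canonical and deterministic: at (i, j) pairing i is
    preferred over leaving it unpaired, trying the nearest partner
    (smallest k - i) first.
    """
    if not seq:
        raise ValidationError("cannot fold an empty sequence")
    if len(seq) > MAX_FOLD_LEN:
        raise CapacityError(f"sequence of {len(seq)} nt exceeds {MAX_FOLD_LEN}")
    bad = set(seq) - set("ACGU")
    if bad:
        raise ValidationError(f"invalid alphabet characters {sorted(bad)!r}")

    n = len(seq)
    min_loop = model.min_loop

    # pair-energy matrix, _INF where unpairable or loop too small
    codes = np.frombuffer(seq.encode(), dtype=np.uint8)
    pairE = np.full((n, n), _INF)
    for (a, b), e in model.pair_energies.items():
        ia, ib = ord(a), ord(b)
        rows = np.nonzero(codes == ia)[0]
        cols = np.nonzero(codes == ib)[0]
        if rows.size and cols.size:
            pairE[np.ix_(rows, cols)] = np.minimum(pairE[np.ix_(rows, cols)], e)
    too_close = np.add.outer(-np.arange(n), np.arange(n)) <= min_loop
    pairE[too_close] = _INF

    # E padded to (n+1) x (n+1): E[a, b] = 0 for empty intervals (a > b).
    # Each antidiagonal is filled in one vectorized step over all split
    # points t (= k - i), which keeps the O(n^3) work inside numpy.
    E = np.zeros((n + 1, n + 1))
    for span in range(min_loop + 1, n):
        ii = np.arange(0, n - span)[:, None]
        tt = np.arange(min_loop + 1, span + 1)[None, :]
        cand = pairE[ii, ii + tt] + E[ii + 1, ii + tt - 1] + E[ii + tt + 1, ii + span]
        i = ii[:, 0]
        E[i, i + span] = np.minimum(E[i + 1, i + span], cand.min(axis=1))

    # canonical traceback
    pair_of: list[Optional[int]] = [None] * n
    stack = [(0, n - 1)]
    tol = 1e-6
    while stack:
        i, j = stack.pop()
        while i < j:
            e_ij = E[i, j]
            if e_ij >= -tol:  # nothing pairable in this interval
                break
            paired = False
            for k in range(i + min_loop + 1, j + 1):
                if pairE[i, k] >= _INF / 2:
                    continue
                if abs(pairE[i, k] + E[i + 1, k - 1] + E[k + 1, j] - e_ij) <= tol:
                    pair_of[i], pair_of[k] = k, i
                    if k + 1 < j + 1:
                        stack.append((k + 1, j))
                    i, j = i + 1, k - 1
                    paired = True
                    break
            if not paired:
                i += 1  # E(i,j) == E(i+1,j)

    db = "".join(
        "." if p is None else ("(" if p > i else ")") for i, p in enumerate(pair_of)
    )
    energy = float(E[0, n - 1]) if n > 1 else 0.0
    return SecondaryStructure(seq, db, energy)


def hairpin_metrics(structure: SecondaryStructure) -> HairpinMetrics:
    """AMFE, MFEI, A+U% and length of a folded sequence.

    AMFE = |MFE| / length x 100; MFEI = AMFE / GC% (GC expressed as a
    percentage, so a typical plant pre-miRNA under a thermodynamic model
    scores around 1).
    """
    L = len(structure.seq)
    mfe_abs = abs(structure.energy)
    amfe = mfe_abs / L * 100.0
    gc = gc_percent(structure.seq)
    mfei = amfe / gc if gc > 0 else None
    return HairpinMetrics(
        mfe_abs=mfe_abs,
        amfe=amfe,
        mfei=mfei,
        au_percent=au_percent(structure.seq),
        gc_percent=gc,
        precursor_len=L,
    )


def is_hairpin(structure: SecondaryStructure) -> tuple[bool, Optional[list[str]]]:
    """Single stem-loop test plus an arm map.

    True iff the structure has exactly one terminal loop (hence no
    multiloop).  The arm map labels each position "5'" (before the terminal
    loop), "loop", or "3'".  Returns (False, None) for structures with zero
    or several terminal loops.
    """
    pairs = structure.pairs()
    if not pairs:
        return False, None
    table = structure.pair_table()
    terminal = [
        (i, j)
        for i, j in pairs
        if all(table[p] is None for p in range(i + 1, j))
    ]
    if len(terminal) != 1:
        return False, None
    i, j = terminal[0]
    arm_map = ["5'"] * (i + 1) + ["loop"] * (j - i - 1) + ["3'"] * (
        len(structure.seq) - j
    )
    return True, arm_map


class NussinovFolder:
    """Default folder: the built-in energy-scored DP."""

    def __init__(self, model: EnergyModel = DEFAULT_MODEL) -> None:
        self.model = model

    def fold(self, seq: str) -> SecondaryStructure:
        return fold_rna(seq, self.model)


class RNAfoldFolder:
    """Adapter that delegates folding to an external ``RNAfold`` binary.

    Thermodynamic energies from this folder are on the nearest-neighbor
    scale, so hairpin-criteria thresholds (notably the MFEI cutoff) must be
    recalibrated when it is used.
    """

    def __init__(self, binary: str = "RNAfold") -> None:
        if shutil.which(binary) is None:
            raise ValidationError(f"{binary!r} not found on PATH")
        self.binary = binary

    def fold(self, seq: str) -> SecondaryStructure:
        out = subprocess.run(
            [self.binary, "--noPS"],
            input=seq + "\n",
            capture_output=True,
            text=True,
            check=True,
        ).stdout.splitlines()
        struct_line = out[1]
        db, _, energy_part = struct_line.partition(" ")
        energy = float(energy_part.strip().strip("()"))
        return SecondaryStructure(seq, db, energy)
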