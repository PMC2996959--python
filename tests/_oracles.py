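"""Independent brute-force oracles used by the tests.

These deliberately avoid the library's dynamic program: structures are
enumerated explicitly as sets of base pairs and scored one by one.
"""

from __future__ import annotations

from srnakit.fold import DEFAULT_MODEL, EnergyModel


def enumerate_structures(
    seq: str, model: EnergyModel = DEFAULT_MODEL
) -> list[frozenset[tuple[int, int]]]:
    """All nested structures of ``seq`` (as frozensets of 0-based pairs)."""
    ml = model.min_loop

    def region(i: int, j: int) -> list[frozenset]:
        if j - i < ml + 1:
            return [frozenset()]
        out = list(region(i + 1, j))  # i unpaired
        for k in range(i + ml + 1, j + 1):
            if (seq[i], seq[k]) not in model.pair_energies:
                continue
            for inner in region(i + 1, k - 1):
                for outer in region(k + 1, j):
                    out.append(inner | outer | {(i, k)})
        return out

    return region(0, len(seq) - 1)


def structure_energy(
    seq: str, pairs: frozenset[tuple[int, int]], model: EnergyModel = DEFAULT_MODEL
) -> float:
    return sum(model.pair_energies[(seq[i], seq[j])] for i, j in pairs)


def brute_force_mfe(seq: str, model: EnergyModel = DEFAULT_MODEL) -> float:
    """Minimum energy over every enumerated nested structure."""
    return min(
        structure_energy(seq, s, model) for s in enumerate_structures(seq, model)
    )


def naive_target_scan(mirna: str, transcript: str, max_mismatch: int):
    """Window-by-window recomputation of target hits, no shortcuts."""
    from srnakit.targets import pair_class

    L = len(mirna)
    hits = []
    for start in range(len(transcript) - L + 1):
        site = transcript[start : start + L]
        mm = wob = 0
        for i in range(L):
            cls = pair_class(mirna[i], site[L - 1 - i])
            if cls == "mismatch":
                mm += 1
            elif cls == "wobble":
                wob += 1
        if mm <= max_mismatch:
            hits.append((start + 1, start + L, mm, wob))
    return hits
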