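"""Independent naive oracle for the binding-site scanner.

Pure-python, per-window enumeration with a direct pairwise overlap filter —
deliberately naive and independent of the vectorized scanner it checks.
"""

from __future__ import annotations

BONDS = {
    frozenset("AU"): 2.0,
    frozenset("CG"): 3.0,
    frozenset("GU"): 2.0,
    frozenset("AC"): 1.0,
}
COMP = {"A": "U", "U": "A", "C": "G", "G": "C"}


def naive_window_bonds(mirna: str, window: str) -> float:
    """Bond total of the miRNA laid antiparallel on the window."""
    total = 0.0
    L = len(mirna)
    for i in range(L):  # miRNA position i (0-based) pairs window L-1-i
        pair = frozenset((mirna[i], window[L - 1 - i]))
        total += BONDS.get(pair, 0.0)
    return total


def naive_scan(mirna: str, transcript: str, min_ratio: float = 80.0) -> list[tuple[int, float]]:
    """All retained (1-based start, ratio) sites after local-max filtering."""
    L = len(mirna)
    max_bonds = sum(BONDS[frozenset((b, COMP[b]))] for b in mirna)
    if max_bonds == 0 or len(transcript) < L:
        return []
    cands = []
    for s in range(len(transcript) - L + 1):
        ratio = 100.0 * naive_window_bonds(mirna, transcript[s : s + L]) / max_bonds
        if ratio >= min_ratio - 1e-9:
            cands.append((s + 1, ratio))
    kept = []
    for start_i, ratio_i in cands:
        beaten = False
        for start_j, ratio_j in cands:
            if start_i == start_j:
                continue
            if abs(start_i - start_j) < L:
                if ratio_j > ratio_i + 1e-9 or (
                    abs(ratio_j - ratio_i) <= 1e-9 and start_j < start_i
                ):
                    beaten = True
                    break
        if not beaten:
            kept.append((start_i, ratio_i))
    return sorted(kept)


def random_rna(rng, length: int) -> str:
    return "".join("ACGU"[i] for i in rng.integers(0, 4, length))
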