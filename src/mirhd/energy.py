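"""Hydrogen-bond free-energy model for full-length miRNA:mRNA duplexes.

The duplex is scored position by position over the *entire* miRNA, with the
miRNA laid antiparallel on the mRNA window: miRNA position ``i`` (5'→3',
1-based) pairs with window position ``L − i + 1``.  Each admissible base pair
contributes a fixed number of hydrogen bonds times a single per-bond free
energy; positions that cannot pair contribute nothing.  Both canonical
(A–U, G–C) and non-canonical (G–U wobble, A–C) pairs are admitted.

ΔGm, the energy of the miRNA bound to its exact reverse complement, depends
only on base composition and normalizes site quality as the percentage
ratio ΔG/ΔGm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping

import numpy as np

from .errors import ContractError

RNA_BASES = "ACGU"
_BASE_INDEX = {b: i for i, b in enumerate(RNA_BASES)}
_COMPLEMENT = str.maketrans("ACGU", "UGCA")

#: hydrogen bonds per admissible pair, keyed by the sorted base pair
DEFAULT_BONDS: Mapping[str, float] = {"AU": 2.0, "CG": 3.0, "GU": 2.0, "AC": 1.0}

#: inter-nucleotide distances (nm); descriptive metadata, no energetic role
DEFAULT_PAIR_DISTANCE_NM: Mapping[str, float] = {
    "AC": 1.04,
    "CG": 1.03,
    "AU": 1.03,
    "GU": 1.02,
}

#: free energy per hydrogen bond, kJ/mol (negative = favourable)
DEFAULT_ENERGY_PER_BOND = -2.1

CANONICAL_PAIRS = frozenset({"AU", "CG"})
NONCANONICAL_PAIRS = frozenset({"GU", "AC"})


def clean_rna(seq: str) -> str:
    """Uppercase, map DNA T→U, and validate against the strict RNA alphabet."""
    s = seq.strip().upper().replace("T", "U")
    bad = set(s) - set(RNA_BASES)
    if bad:
        raise ContractError(f"non-RNA characters in sequence: {sorted(bad)}")
    return s


def revcomp(seq: str) -> str:
    """Reverse complement of an RNA sequence (A↔U, G↔C)."""
    return clean_rna(seq).translate(_COMPLEMENT)[::-1]


def pair_key(a: str, b: str) -> str:
    """Canonical dictionary key for an unordered base pair."""
    return "".join(sorted((a, b)))


@dataclass(frozen=True)
class EnergyModel:
    """Per-pair hydrogen-bond counts and a single per-bond free energy.

    Parameters
    ----------
    bonds_per_pair
        Hydrogen bonds for each admissible pair, keyed by sorted pair
        (``"AU"``, ``"CG"``, ``"GU"``, ``"AC"``).  Pairs absent from the map
        are mismatches and contribute zero.
    energy_per_bond
        Free energy per hydrogen bond in kJ/mol; must be ≤ 0.
    pair_distance_nm
        Inter-nucleotide distances, carried as metadata for pairing schemes.
    """

    bonds_per_pair: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BONDS)
    )
    energy_per_bond: float = DEFAULT_ENERGY_PER_BOND
    pair_distance_nm: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PAIR_DISTANCE_NM)
    )

    def __post_init__(self) -> None:
        if self.energy_per_bond > 0:
            raise ContractError("energy_per_bond must be ≤ 0 (favourable binding)")
        missing = {"AU", "CG", "GU", "AC"} - set(self.bonds_per_pair)
        if missing:
            raise ContractError(f"bonds_per_pair missing pairs: {sorted(missing)}")
        if any(v < 0 for v in self.bonds_per_pair.values()):
            raise ContractError("hydrogen-bond counts must be ≥ 0")

    def bond_matrix(self) -> np.ndarray:
        """4×4 symmetric matrix of bond counts indexed by A,C,G,U codes."""
        return _bond_matrix(tuple(sorted(self.bonds_per_pair.items())))

    def bonds(self, a: str, b: str) -> float:
        """Hydrogen bonds formed by the unordered pair (a, b); 0 if mismatch."""
        return self.bonds_per_pair.get(pair_key(a, b), 0.0)

    def glyph(self, a: str, b: str) -> str:
        """Scheme glyph: '|' canonical, ':' non-canonical, ' ' mismatch."""
        key = pair_key(a, b)
        if key in CANONICAL_PAIRS:
            return "|"
        if key in NONCANONICAL_PAIRS and key in self.bonds_per_pair:
            return ":"
        return " "


@lru_cache(maxsize=None)
def _bond_matrix(items: tuple) -> np.ndarray:
    m = np.zeros((4, 4))
    for key, bonds in items:
        i, j = _BASE_INDEX[key[0]], _BASE_INDEX[key[1]]
        m[i, j] = m[j, i] = bonds
    m.setflags(write=False)
    return m


def encode(seq: str) -> np.ndarray:
    """Integer-encode an RNA sequence (A=0, C=1, G=2, U=3)."""
    return np.array([_BASE_INDEX[b] for b in seq], dtype=np.int64)


def duplex_energy(mirna_seq: str, window: str, model: EnergyModel | None = None) -> float:
    """ΔG (kJ/mol) of the miRNA laid antiparallel on an equal-length mRNA window.

    miRNA position ``i`` (5'→3') pairs with window position ``L − i + 1``;
    unpairable combinations contribute 0.
    """
    model = model or EnergyModel()
    m = clean_rna(mirna_seq)
    w = clean_rna(window)
    if len(m) != len(w):
        raise ContractError(
            f"window length {len(w)} != miRNA length {len(m)}"
        )
    total_bonds = sum(model.bonds(a, b) for a, b in zip(m, reversed(w)))
    return total_bonds * model.energy_per_bond


def max_duplex_energy(mirna_seq: str, model: EnergyModel | None = None) -> float:
    """ΔGm: ΔG of the miRNA against its exact reverse complement.

    Depends only on base composition (every A or U pairs canonically at
    2 bonds, every G or C at 3 under the defaults).
    """
    return duplex_energy(mirna_seq, revcomp(mirna_seq), model)
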