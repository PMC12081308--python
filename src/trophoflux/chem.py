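"""Peptide elemental composition and aggregated isotopologue envelopes.

The MS1 quantities this package works with are *aggregated* (nominal-mass)
isotopologue intensities: M is the all-light monoisotopic species, M1 the
+1 Da pool (one heavy atom of any element), M2 the +2 Da pool, and so on.
Incorporation of a 13C2-acetyl group from U-13C glucose shifts a peptide's
envelope by exactly +2 Da, so separating metabolic label from natural
heavy-isotope abundance requires the theoretical natural envelope of each
peptidoform. That envelope is computed here by convolving per-element
isotope distributions, one convolution per atom group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from pyteomics import mass as _pt_mass

__all__ = [
    "ElementalFormula",
    "Peptidoform",
    "MOD_FORMULAS",
    "peptide_formula",
    "natural_isotope_distribution",
    "UnknownResidueError",
    "UnknownModificationError",
]

# Isotope abundances (IUPAC 2013), indexed by nominal mass offset from the
# lightest isotope. Trailing zeros matter for S (no +3 isotope).
ISOTOPE_ABUNDANCES: dict[str, tuple[float, ...]] = {
    "C": (0.9893, 0.0107),
    "H": (0.999885, 0.000115),
    "N": (0.99636, 0.00364),
    "O": (0.99757, 0.00038, 0.00205),
    "S": (0.9499, 0.0075, 0.0425, 0.0, 0.0001),
}

# Mass deltas of the supported histone modifications. The heavy-Arg label
# (13C6;15N4 SpikeTides) changes isotopes, not the elemental formula; it is
# carried as a flag and contributes no compositional delta.
MOD_FORMULAS: dict[str, dict[str, int]] = {
    "ac": {"C": 2, "H": 2, "O": 1},
    "me1": {"C": 1, "H": 2},
    "me2": {"C": 2, "H": 4},
    "me3": {"C": 3, "H": 6},
    "heavy-Arg-label": {},
}


class UnknownResidueError(KeyError):
    """Amino-acid code outside the 20 canonical residues."""


class UnknownModificationError(KeyError):
    """Modification name outside the supported vocabulary."""


@dataclass(frozen=True)
class ElementalFormula:
    """Non-negative atom counts over the supported elements C, H, N, O, S."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        clean = {}
        for el, n in dict(self.counts).items():
            if el not in ISOTOPE_ABUNDANCES:
                raise ValueError(f"unsupported element: {el!r}")
            if n < 0:
                raise ValueError(f"negative atom count for {el}")
            if n:
                clean[el] = int(n)
        if not clean:
            raise ValueError("formula must contain at least one atom")
        object.__setattr__(self, "counts", clean)

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __add__(self, other: "ElementalFormula | Mapping[str, int]") -> "ElementalFormula":
        other_counts = other.counts if isinstance(other, ElementalFormula) else other
        merged = dict(self.counts)
        for el, n in other_counts.items():
            merged[el] = merged.get(el, 0) + n
        return ElementalFormula(merged)


@dataclass(frozen=True)
class Peptidoform:
    """A peptide sequence plus a set of positioned modifications.

    Positions are 1-based residue indices into ``sequence``. The modification
    vocabulary is closed (``MOD_FORMULAS``); at most one modification per
    position.
    """

    sequence: str
    modifications: tuple[tuple[int, str], ...] = field(default_factory=tuple)
    charge: int = 2

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty sequence")
        object.__setattr__(self, "modifications", tuple(self.modifications))
        seen = set()
        for pos, name in self.modifications:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(f"modification position {pos} outside sequence")
            if pos in seen:
                raise ValueError(f"multiple modifications at position {pos}")
            seen.add(pos)
            if name not in MOD_FORMULAS:
                raise UnknownModificationError(name)
        if self.charge < 1:
            raise ValueError("charge must be positive")

    @property
    def is_heavy_standard(self) -> bool:
        return any(name == "heavy-Arg-label" for _, name in self.modifications)

    def n_acetyl(self) -> int:
        return sum(1 for _, name in self.modifications if name == "ac")

    def mod_string(self) -> str:
        """Compact dialect like ``"K27ac;K36me2"`` using 1-based positions."""
        parts = [
            f"{self.sequence[pos - 1]}{pos}{name}"
            for pos, name in sorted(self.modifications)
            if name != "heavy-Arg-label"
        ]
        if self.is_heavy_standard:
            parts.append("heavy")
        return ";".join(parts) if parts else "unmod"


def peptide_formula(p: Peptidoform) -> ElementalFormula:
    """Elemental formula: residue compositions + one water + modification deltas.

    Residue compositions come from the standard amino-acid table; unknown
    residues raise :class:`UnknownResidueError`.
    """
    counts: dict[str, int] = {"H": 2, "O": 1}  # the terminal water
    for aa in p.sequence:
        try:
            comp = _pt_mass.std_aa_comp[aa]
        except KeyError as exc:
            raise UnknownResidueError(aa) from exc
        for el, n in comp.items():
            counts[el] = counts.get(el, 0) + n
    for _, name in p.modifications:
        for el, n in MOD_FORMULAS[name].items():
            counts[el] = counts.get(el, 0) + n
    return ElementalFormula(counts)


def natural_isotope_distribution(
    f: ElementalFormula, n: int
) -> tuple[np.ndarray, float]:
    """Aggregated isotopologue probabilities P(M), P(M1), ... P(M_{n-1}).

    Computed by iterated convolution of the per-element isotope
    distributions: an element with k atoms contributes its single-atom
    distribution convolved with itself k times (done by exponentiation by
    squaring on truncated arrays, which is exact for the first ``n`` terms
    because convolution cannot move probability to lower mass offsets).

    Returns the length-``n`` probability array and the truncated tail mass
    ``1 - sum(probabilities)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    env = np.zeros(n)
    env[0] = 1.0
    for el, count in f.counts.items():
        single = np.zeros(n)
        dist = ISOTOPE_ABUNDANCES[el][:n]
        single[: len(dist)] = dist
        env = _trunc_convolve(env, _power(single, count, n), n)
    tail = 1.0 - env.sum()
    return env, max(tail, 0.0)


def _trunc_convolve(a: np.ndarray, b: np.ndarray, n: int) -> np.ndarray:
    return np.convolve(a, b)[:n]


def _power(dist: np.ndarray, k: int, n: int) -> np.ndarray:
    out = np.zeros(n)
    out[0] = 1.0
    base = dist.copy()
    while k:
        if k & 1:
            out = _trunc_convolve(out, base, n)
        k >>= 1
        if k:
            base = _trunc_convolve(base, base, n)
    return out


def parse_mod_string(sequence: str, mods: str, offset: int = 0) -> tuple[tuple[int, str], ...]:
    """Parse ``"K27ac;K36me2"``-style strings into (position, name) pairs.

    ``offset`` maps protein residue numbering to the peptide (e.g. a peptide
    starting at protein residue 18 has ``offset=17``). ``"unmod"`` or the
    empty string mean no modifications; a bare ``"heavy"`` token marks the
    heavy-arginine spike-in standard.
    """
    if not mods or mods == "unmod":
        return ()
    out = []
    for token in mods.split(";"):
        token = token.strip()
        if not token:
            continue
        if token == "heavy":
            # attach to the last residue (the labelled arginine in SpikeTides)
            out.append((len(sequence), "heavy-Arg-label"))
            continue
        i = 1
        while i < len(token) and token[i].isdigit():
            i += 1
        if i == 1:
            raise ValueError(f"malformed modification token: {token!r}")
        pos = int(token[1:i]) - offset
        name = token[i:]
        if name not in MOD_FORMULAS:
            raise UnknownModificationError(name)
        expected = token[0]
        if not 1 <= pos <= len(sequence) or sequence[pos - 1] != expected:
            raise ValueError(
                f"token {token!r} does not match sequence {sequence!r} at offset {offset}"
            )
        out.append((pos, name))
    return tuple(out)
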