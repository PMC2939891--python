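"""Additive binding-energy scoring under a sequence-to-structure register.

A peptide of length n can sit in the 10-position SH3 binding groove in
several registers.  Register ("offset") k assigns structural position i the
sequence residue j = i - k, when 1 <= j <= n; other positions stay
unassigned and contribute zero energy.  Offset 0 is the canonical mapping
(P1, S1) ... (P10, S10); offset -1 shifts the peptide one residue toward its
N terminus, (P1, S2) ... (P10, S11).

Also houses detection of the two canonical proline-rich SH3 ligand motifs:
class I (R/K)xxPxxP and class II PxxPx(R/K), which determine the peptide
binding orientation.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .matrixio import AA_INDEX, N_POSITIONS, EnergyMatrix, _check_sequence

DEFAULT_OFFSETS = range(-4, 5)

CLASS_I_PATTERN = re.compile(r"[RK]..P..P")
CLASS_II_PATTERN = re.compile(r"P..P.[RK]")


class MotifClass(enum.Enum):
    """Canonical SH3 ligand motif class of a peptide sequence."""

    I = "I"
    II = "II"
    BOTH = "both"
    NONE = "none"


def detect_motif_class(sequence: str) -> MotifClass:
    """Classify ``sequence`` by the canonical motifs it contains.

    Class I matches ``[RK]..P..P`` anywhere, class II matches ``P..P.[RK]``;
    a sequence matching both (or neither) is reported as such.
    """
    _check_sequence(sequence, "sequence")
    has_i = CLASS_I_PATTERN.search(sequence) is not None
    has_ii = CLASS_II_PATTERN.search(sequence) is not None
    if has_i and has_ii:
        return MotifClass.BOTH
    if has_i:
        return MotifClass.I
    if has_ii:
        return MotifClass.II
    return MotifClass.NONE


@dataclass(frozen=True)
class SequenceMapping:
    """Assignment of a peptide's residues to structural positions.

    ``residues[i-1]`` is the residue placed at position i, or ``None`` when
    the register leaves that position uncovered.
    """

    sequence: str
    offset: int
    residues: tuple[Optional[str], ...]

    @property
    def n_assigned(self) -> int:
        return sum(r is not None for r in self.residues)


def map_sequence(
    sequence: str, offset: int, n_positions: int = N_POSITIONS
) -> SequenceMapping:
    """Place ``sequence`` on the structural positions at register ``offset``.

    Position i receives residue j = i - offset when 1 <= j <= len(sequence).
    """
    _check_sequence(sequence, "sequence")
    residues = []
    for i in range(1, n_positions + 1):
        j = i - offset
        residues.append(sequence[j - 1] if 1 <= j <= len(sequence) else None)
    return SequenceMapping(sequence=sequence, offset=offset, residues=tuple(residues))


def score_mapping(matrix: EnergyMatrix, mapping: SequenceMapping) -> float:
    """Sum the matrix entries at the assigned positions (unassigned add 0)."""
    total = 0.0
    for i, residue in enumerate(mapping.residues):
        if residue is not None:
            total += float(matrix.values[AA_INDEX[residue], i])
    return total


def offset_preference_order(offsets: Iterable[int]) -> list[int]:
    """Offsets sorted by tie-break preference: |offset| ascending, then negative."""
    return sorted(offsets, key=lambda o: (abs(o), o))


def best_offset(
    matrix: EnergyMatrix,
    sequence: str,
    offsets: Iterable[int] = DEFAULT_OFFSETS,
) -> tuple[int, float]:
    """Register minimizing the additive energy against ``matrix``.

    Ties are broken toward the offset closest to 0, then toward the more
    negative offset, so results are deterministic.
    """
    candidates = offset_preference_order(offsets)
    if not candidates:
        raise ValueError("offset range must be non-empty")
    best_o: Optional[int] = None
    best_e = np.inf
    for o in candidates:
        e = score_mapping(matrix, map_sequence(sequence, o, matrix.values.shape[1]))
        if e < best_e:
            best_o, best_e = o, e
    assert best_o is not None
    return best_o, best_e
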