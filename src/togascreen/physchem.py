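"""Sequence-intrinsic physicochemical calculations.

Average molecular weight (ProtParam-style), amino-acid composition, and
Kyte-Doolittle hydropathy profiles. All scales are constants shipped as
package data (:mod:`togascreen._tables`).

Two hydrophobic-residue sets are defined for the C-terminal anchoring
signature. ``kd_positive`` is the set with positive Kyte-Doolittle values,
{A,C,F,I,L,M,V}. ``extended`` additionally counts the aromatics W and Y,
which sit in the membrane interface region of beta-barrels and are treated
as hydrophobic in published porin C-terminus comparisons; it is the default
for the anchoring-signature rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._tables import (
    CANONICAL_RESIDUES,
    KYTE_DOOLITTLE,
    RESIDUE_MASSES,
    WATER_MASS,
)
from .seqio import ProteinRecord

KD_POSITIVE_SET = frozenset("ACFILMV")
EXTENDED_SET = KD_POSITIVE_SET | frozenset("WY")

HYDROPHOBIC_SETS: dict[str, frozenset[str]] = {
    "kd_positive": KD_POSITIVE_SET,
    "extended": EXTENDED_SET,
}


@dataclass(frozen=True)
class MassResult:
    """Average (not monoisotopic) mass of a peptide chain."""

    average_mass: float  # daltons
    n_residues: int

    @property
    def kda(self) -> float:
        return self.average_mass / 1000.0


@dataclass(frozen=True)
class CompositionProfile:
    """Per-residue counts and fractions over counted residues.

    ``X`` residues (when admitted at parse time) are excluded from both
    counts and the fraction denominator.
    """

    counts: dict[str, int]
    fraction: dict[str, float]
    n_counted: int


@dataclass(frozen=True)
class HydropathyProfile:
    per_residue: list[float]
    windowed: list[float]
    window: int


def _counted(sequence: str) -> str:
    # X is the only non-canonical residue that can reach this layer
    return sequence.replace("X", "")


def compute_mw(record: ProteinRecord) -> MassResult:
    """Average molecular weight: sum of residue masses plus one water.

    Matches ProtParam's convention (Expasy average-isotopic residue masses).
    A single glycine comes to 75.07 Da.
    """
    seq = _counted(record.sequence)
    if not seq:
        raise ValueError(f"record {record.id!r}: no canonical residues to weigh")
    mass = sum(RESIDUE_MASSES[aa] for aa in seq) + WATER_MASS
    return MassResult(average_mass=mass, n_residues=len(record.sequence))


def composition(record: ProteinRecord) -> CompositionProfile:
    """Amino-acid counts and fractions; fractions sum to 1 over counted residues."""
    seq = _counted(record.sequence)
    if not seq:
        raise ValueError(f"record {record.id!r}: empty sequence")
    counts = {aa: 0 for aa in CANONICAL_RESIDUES}
    for aa in seq:
        counts[aa] += 1
    n = len(seq)
    fraction = {aa: c / n for aa, c in counts.items()}
    return CompositionProfile(counts=counts, fraction=fraction, n_counted=n)


def hydropathy_profile(record: ProteinRecord, window: int = 9) -> HydropathyProfile:
    """Kyte-Doolittle per-residue values and sliding-window means.

    The window must be odd and positive. With n residues and window w the
    windowed track has n - w + 1 points (empty when n < w); window 1 is the
    identity. X residues score 0 (non-hydrophobic).
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    values = [KYTE_DOOLITTLE.get(aa, 0.0) for aa in record.sequence]
    n = len(values)
    if n >= window:
        arr = np.asarray(values)
        kernel = np.ones(window) / window
        windowed = list(np.convolve(arr, kernel, mode="valid"))
    else:
        windowed = []
    return HydropathyProfile(per_residue=values, windowed=windowed, window=window)


def is_hydrophobic(residue: str, set_name: str = "extended") -> bool:
    """Membership of a residue in the named hydrophobic set.

    ``kd_positive``: Kyte-Doolittle value > 0, i.e. {A,C,F,I,L,M,V}.
    ``extended``: kd_positive plus {W,Y}.
    X never counts as hydrophobic.
    """
    if set_name not in HYDROPHOBIC_SETS:
        raise ValueError(f"unknown hydrophobic set {set_name!r}")
    if residue == "X":
        return False
    if residue not in CANONICAL_RESIDUES:
        raise ValueError(f"unknown residue {residue!r}")
    return residue in HYDROPHOBIC_SETS[set_name]
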