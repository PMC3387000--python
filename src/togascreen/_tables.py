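"""Loaders for the constant tables shipped as package data.

Every numeric scale the predictors use (hydropathy, residue masses,
secondary-structure propensities, disorder propensities, background
composition, published reference decamers) lives in a plain-text TSV under
``togascreen/data`` so the constants are inspectable without reading code.
Tables are parsed once at import time into plain dicts.
"""

from __future__ import annotations

from importlib import resources
from typing import Iterator

CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: Mass of one water molecule in daltons, added once per peptide chain.
WATER_MASS = 18.01528


def _rows(filename: str) -> Iterator[list[str]]:
    text = (resources.files("togascreen") / "data" / filename).read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        yield line.split("\t")


def _load_scale(filename: str, column: int = 1) -> dict[str, float]:
    table = {}
    for row in _rows(filename):
        if row[0] == "residue":  # header
            continue
        table[row[0]] = float(row[column])
    missing = set(CANONICAL_RESIDUES) - table.keys()
    if missing:
        raise RuntimeError(f"{filename} is missing residues {sorted(missing)}")
    return table


#: Kyte-Doolittle hydropathy values.
KYTE_DOOLITTLE: dict[str, float] = _load_scale("kyte_doolittle.tsv")

#: Expasy average residue masses (Da), water excluded.
RESIDUE_MASSES: dict[str, float] = _load_scale("residue_masses.tsv")

#: Chou-Fasman helix propensities P(alpha).
CF_HELIX: dict[str, float] = _load_scale("chou_fasman.tsv", column=1)

#: Chou-Fasman strand propensities P(beta).
CF_STRAND: dict[str, float] = _load_scale("chou_fasman.tsv", column=2)

#: Russell/Linding disorder propensities.
DISORDER: dict[str, float] = _load_scale("disorder_russell_linding.tsv")

#: Mean of the 20 disorder propensities; the running-sum detector centres
#: per-residue propensities on this constant.
DISORDER_MEAN: float = sum(DISORDER.values()) / len(DISORDER)

_bg = _load_scale("swissprot_background.tsv")
_total = sum(_bg.values())
#: Swiss-Prot average composition, normalised to fractions.
SWISSPROT_BACKGROUND: dict[str, float] = {aa: v / _total for aa, v in _bg.items()}


def load_reference_decamers() -> list[dict[str, str]]:
    """Published C-terminal decamers of porins and OmpB orthologs/analogs.

    Returns a list of dicts with keys ``name``, ``organism``, ``group``
    (``known_porin`` | ``ortholog`` | ``analog``) and ``decamer`` (the last
    ten residues written N->C).
    """
    out = []
    for row in _rows("reference_decamers.tsv"):
        if row[0] == "name":
            continue
        out.append(
            {"name": row[0], "organism": row[1], "group": row[2], "decamer": row[3]}
        )
    return out
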