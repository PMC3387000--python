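"""Screen configuration: every tunable threshold with its default.

Defaults encode the screen's published logic: a 35-50 kDa size window
centred on the ~42 kDa reported porin monomer, the extended hydrophobic
set and relaxed C-terminus mode (the only combination consistent with the
published decamer tables), a +/-0.05 tolerance on the relative beta-strand
range, and an 8/13 composition-bias threshold. A YAML file can override
any field.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import yaml


@dataclass(frozen=True)
class ScreenConfig:
    # size criterion (kDa)
    size_min: float = 35.0
    size_max: float = 50.0
    size_center: float = 42.0  # ranking tie-break only

    # C-terminal anchoring signature
    hydrophobic_set: str = "extended"  # "extended" | "kd_positive"
    cterm_mode: str = "relaxed"  # "relaxed" | "strict"

    # beta-range criterion
    beta_tolerance: float = 0.05

    # composition-bias score
    composition_threshold: float = 8 / 13

    # signal-peptide heuristic
    signal_h_window: int = 7
    signal_h_kd_min: float = 1.6
    signal_site_min: int = 10
    signal_site_max: int = 45

    # globularity detector
    glob_smooth_window: int = 15
    glob_min_domain_len: int = 40
    glob_coverage_min: float = 0.5

    # ingest
    allow_x: bool = False

    # synteny / family clustering
    synteny_pattern: tuple[str, ...] = ("secG", "tyrS", "ompA", "ompB")
    synteny_max_gap: int = 0
    identity_threshold: float = 0.30
    gap_open: int = 11
    gap_extend: int = 1

    def __post_init__(self) -> None:
        if self.hydrophobic_set not in ("extended", "kd_positive"):
            raise ValueError(f"unknown hydrophobic_set {self.hydrophobic_set!r}")
        if self.cterm_mode not in ("relaxed", "strict"):
            raise ValueError(f"unknown cterm_mode {self.cterm_mode!r}")
        if self.size_min >= self.size_max:
            raise ValueError("size_min must be below size_max")


def load_config(path: str | None = None, **overrides) -> ScreenConfig:
    """Build a :class:`ScreenConfig` from an optional YAML file plus overrides.

    YAML keys mirror the dataclass fields; unknown keys are rejected so a
    typo cannot silently leave a threshold at its default.
    """
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a YAML mapping")
        values.update(loaded)
    values.update(overrides)
    known = {f.name for f in fields(ScreenConfig)}
    unknown = set(values) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "synteny_pattern" in values:
        values["synteny_pattern"] = tuple(values["synteny_pattern"])
    return ScreenConfig(**values)
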