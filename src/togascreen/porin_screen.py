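"""The candidate screen: five sequence criteria and the >=3-of-5 caller.

A porin candidate is a protein meeting at least three of five criteria:

1. **size** — average molecular weight inside a window around the reported
   ~42 kDa porin monomer (default 35-50 kDa);
2. **signal** — a Sec signal peptide (rule-based heuristic);
3. **beta** — beta-strand content inside the range spanned by reference
   porins, all evaluated by the same internal predictor (absolute
   percentages from external tools are not comparable across predictors,
   so the criterion is deliberately relative);
4. **globularity** — disorder running-sum detector calls the chain compact;
5. **C-terminus** — the anchoring signature: a terminal phenylalanine plus
   hydrophobic residues at alternating positions of the last decamer.

A protein meeting all five is a *strong* candidate. Alongside the five
criteria the module scores the porin composition bias (low Arg/Cys/Glu/
His/Ile/Met/Pro/Trp, high Ala/Gly/Asn/Asp/Leu relative to a background
composition).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from ._tables import SWISSPROT_BACKGROUND
from .config import ScreenConfig
from .physchem import (
    CompositionProfile,
    composition,
    compute_mw,
    is_hydrophobic,
)
from .seqio import ProteinRecord
from .structure_pred import (
    SecondaryStructureSummary,
    assess_globularity,
    detect_signal_peptide,
    predict_secondary_structure,
)

#: Residues porins are depleted in.
LOW_SET = ("R", "C", "E", "H", "I", "M", "P", "W")
#: Residues porins are enriched in.
HIGH_SET = ("A", "G", "N", "D", "L")

#: Odd decamer positions (counted from the C-terminus) that carry the
#: alternating hydrophobic face of the anchoring beta-strand.
ODD_POSITIONS = (3, 5, 7, 9)


@dataclass(frozen=True)
class CTerminusReport:
    """Classification of the last ten residues against the anchoring signature.

    ``decamer`` is written N->C; position 1 is the C-terminal residue and
    positions ascend toward the N-terminus, so position i is
    ``decamer[-i]``. ``hydrophobic_mask[i-1]`` answers "is position i
    hydrophobic" under the configured set.
    """

    decamer: str
    terminal_is_F: bool
    hydrophobic_mask: tuple[bool, ...]
    odd_positions_hydrophobic: int
    passes_strict: bool
    passes_relaxed: bool
    hydrophobic_set: str
    too_short: bool = False

    def passes(self, mode: str) -> bool:
        return self.passes_strict if mode == "strict" else self.passes_relaxed


@dataclass(frozen=True)
class CompositionReport:
    low_set_ok: tuple[str, ...]
    high_set_ok: tuple[str, ...]
    score: float
    porin_like: bool


@dataclass(frozen=True)
class CriterionVector:
    """The five boolean criteria plus supporting values for one protein."""

    size_ok: bool
    signal_ok: bool
    beta_ok: bool
    globular_ok: bool
    cterm_ok: bool
    mw_kda: float
    beta_frac: float
    n_true: int
    candidate: bool
    strong: bool

    @classmethod
    def from_flags(
        cls,
        size_ok: bool,
        signal_ok: bool,
        beta_ok: bool,
        globular_ok: bool,
        cterm_ok: bool,
        mw_kda: float = 0.0,
        beta_frac: float = 0.0,
    ) -> "CriterionVector":
        """Derive the candidate call from the five flags.

        ``candidate`` iff at least three criteria hold; ``strong`` iff all
        five do. This is the only place the counting rule lives.
        """
        flags = (size_ok, signal_ok, beta_ok, globular_ok, cterm_ok)
        n_true = sum(flags)
        return cls(
            *flags,
            mw_kda=mw_kda,
            beta_frac=beta_frac,
            n_true=n_true,
            candidate=n_true >= 3,
            strong=n_true == 5,
        )


def classify_cterminus(
    record: ProteinRecord,
    hydrophobic_set: str = "extended",
    mode: str = "relaxed",
) -> CTerminusReport:
    """Classify the C-terminal decamer against the porin anchoring signature.

    Strict pass: terminal phenylalanine AND hydrophobic residues at all of
    positions 3, 5, 7 and 9 (counted from the C-terminus). Relaxed pass:
    terminal phenylalanine AND at least 3 of those four positions
    hydrophobic. Published ortholog tables include entries with exactly one
    non-hydrophobic odd position that are still scored as porin-like, which
    is why relaxed is the default mode. The report depends only on the last
    ten residues.
    """
    if mode not in ("strict", "relaxed"):
        raise ValueError(f"unknown mode {mode!r}")
    seq = record.sequence
    if len(seq) < 10:
        return CTerminusReport(
            decamer=seq,
            terminal_is_F=False,
            hydrophobic_mask=(),
            odd_positions_hydrophobic=0,
            passes_strict=False,
            passes_relaxed=False,
            hydrophobic_set=hydrophobic_set,
            too_short=True,
        )
    decamer = seq[-10:]
    mask = tuple(is_hydrophobic(decamer[-i], hydrophobic_set) for i in range(1, 11))
    terminal_is_F = decamer[-1] == "F"
    n_odd = sum(mask[i - 1] for i in ODD_POSITIONS)
    return CTerminusReport(
        decamer=decamer,
        terminal_is_F=terminal_is_F,
        hydrophobic_mask=mask,
        odd_positions_hydrophobic=n_odd,
        passes_strict=terminal_is_F and n_odd == 4,
        passes_relaxed=terminal_is_F and n_odd >= 3,
        hydrophobic_set=hydrophobic_set,
    )


def composition_porin_score(
    profile: CompositionProfile,
    background: dict[str, float] | None = None,
    threshold: float = 8 / 13,
) -> CompositionReport:
    """Score the porin composition bias against a background composition.

    A low-set residue counts when its fraction is strictly below the
    background fraction; a high-set residue when strictly above. The score
    is the fraction of the 13 diagnostic residues that agree with the porin
    bias; ``porin_like`` at >= ``threshold`` (default 8/13). The default
    background is the Swiss-Prot average composition shipped as package
    data.
    """
    if background is None:
        background = SWISSPROT_BACKGROUND
    for aa in LOW_SET + HIGH_SET:
        if background.get(aa, 0.0) <= 0.0 and profile.fraction.get(aa, 0.0) > 0.0:
            raise ValueError(
                f"background composition has no mass for residue {aa!r}"
            )
    low_ok = tuple(
        aa for aa in LOW_SET if profile.fraction.get(aa, 0.0) < background[aa]
    )
    high_ok = tuple(
        aa for aa in HIGH_SET if profile.fraction.get(aa, 0.0) > background[aa]
    )
    score = (len(low_ok) + len(high_ok)) / 13
    return CompositionReport(
        low_set_ok=low_ok,
        high_set_ok=high_ok,
        score=score,
        porin_like=score >= threshold,
    )


def beta_range_criterion(
    query: SecondaryStructureSummary,
    references: Sequence[SecondaryStructureSummary],
    tolerance: float = 0.05,
) -> bool:
    """Is the query's strand fraction inside the reference range (+/- tolerance)?

    References must come from the same predictor as the query; at least two
    are required for a meaningful range.
    """
    if len(references) < 2:
        raise ValueError("beta_range_criterion needs at least 2 references")
    fracs = [r.frac_E for r in references]
    return min(fracs) - tolerance <= query.frac_E <= max(fracs) + tolerance


def _reference_summaries(
    references: Sequence[ProteinRecord],
) -> list[SecondaryStructureSummary]:
    return [predict_secondary_structure(r) for r in references]


def evaluate_candidate(
    record: ProteinRecord,
    references: Sequence[ProteinRecord],
    config: ScreenConfig | None = None,
    _ref_summaries: Sequence[SecondaryStructureSummary] | None = None,
) -> CriterionVector:
    """Evaluate all five criteria for one protein.

    Component failures on degenerate sequences (too short for a decamer,
    for a signal peptide, ...) yield a false criterion, never an abort:
    the screen must run proteome-wide. ``_ref_summaries`` lets
    :func:`screen_proteome` reuse reference predictions across records.
    """
    if not references and _ref_summaries is None:
        raise ValueError("evaluate_candidate requires reference porins")
    cfg = config or ScreenConfig()
    refs = (
        list(_ref_summaries)
        if _ref_summaries is not None
        else _reference_summaries(references)
    )

    mass = compute_mw(record)
    size_ok = cfg.size_min <= mass.kda <= cfg.size_max

    signal = detect_signal_peptide(
        record,
        h_window=cfg.signal_h_window,
        h_kd_min=cfg.signal_h_kd_min,
        site_min=cfg.signal_site_min,
        site_max=cfg.signal_site_max,
    )

    ss = predict_secondary_structure(record)
    beta_ok = beta_range_criterion(ss, refs, tolerance=cfg.beta_tolerance)

    glob = assess_globularity(
        record,
        smooth_window=cfg.glob_smooth_window,
        min_domain_len=cfg.glob_min_domain_len,
        coverage_min=cfg.glob_coverage_min,
    )

    cterm = classify_cterminus(
        record, hydrophobic_set=cfg.hydrophobic_set, mode=cfg.cterm_mode
    )

    return CriterionVector.from_flags(
        size_ok=size_ok,
        signal_ok=signal.present,
        beta_ok=beta_ok,
        globular_ok=glob.globular,
        cterm_ok=cterm.passes(cfg.cterm_mode),
        mw_kda=mass.kda,
        beta_frac=ss.frac_E,
    )


def screen_proteome(
    records: Iterable[ProteinRecord],
    references: Sequence[ProteinRecord],
    config: ScreenConfig | None = None,
) -> list[tuple[ProteinRecord, CriterionVector]]:
    """Screen every record and rank the results.

    Ordering: criteria met (descending), then distance of the molecular
    weight from the expected porin monomer size, then id — fully
    deterministic and independent of input order.
    """
    cfg = config or ScreenConfig()
    ref_summaries = _reference_summaries(references)
    results = [
        (rec, evaluate_candidate(rec, references, cfg, _ref_summaries=ref_summaries))
        for rec in records
    ]
    results.sort(
        key=lambda rv: (-rv[1].n_true, abs(rv[1].mw_kda - cfg.size_center), rv[0].id)
    )
    return results
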