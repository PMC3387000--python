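"""Internal heuristic structure predictors.

Three single-sequence predictors stand behind three of the five screening
criteria:

* :func:`predict_secondary_structure` — the classic Chou-Fasman
  nucleation/extension procedure; its strand fraction is the screen's
  "beta-strand content". Beta content is only ever compared *relatively*,
  candidate versus reference proteins run through this same predictor.
* :func:`detect_signal_peptide` — a rule-based Sec signal heuristic
  (charged n-region, hydrophobic h-region, small-residue (-3,-1)
  cleavage-site rule).
* :func:`assess_globularity` — a disorder-propensity running-sum detector
  in the spirit of GlobPlot: smoothed downhill stretches of the cumulative
  Russell/Linding propensity are globular domains.

All three are deterministic pure functions of the sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._tables import CF_HELIX, CF_STRAND, DISORDER, DISORDER_MEAN, KYTE_DOOLITTLE
from .seqio import ProteinRecord


@dataclass(frozen=True)
class SecondaryStructureSummary:
    """Per-residue H/E/C labels and state fractions (summing to 1)."""

    states: str
    frac_H: float
    frac_E: float
    frac_C: float
    method: str = "chou_fasman"
    too_short: bool = False


@dataclass(frozen=True)
class SignalPeptideCall:
    present: bool
    cleavage_after: int | None  # 1-based residue index, or None
    h_region: tuple[int, int] | None  # 1-based inclusive interval
    score: float
    too_short: bool = False


@dataclass(frozen=True)
class GlobularityCall:
    globular: bool
    domains: tuple[tuple[int, int], ...]  # 1-based inclusive residue intervals
    coverage: float


# --- Chou-Fasman ----------------------------------------------------------

_H_NUC_WIN, _H_NUC_COUNT = 6, 4  # helix: 4 of 6 with P(H) > 1.00
_E_NUC_WIN, _E_NUC_COUNT = 5, 3  # strand: 3 of 5 with P(E) > 1.00
_EXT_WIN = 4  # extension: window-4 mean propensity >= 1.00


def _propensities(sequence: str, table: dict[str, float]) -> np.ndarray:
    # X gets the indifferent level 1.0 so it neither nucleates nor breaks
    return np.array([table.get(aa, 1.0) for aa in sequence])


def _nucleate_and_extend(
    vals: np.ndarray, nuc_win: int, nuc_count: int
) -> list[tuple[int, int]]:
    """Nucleation windows merged, then extended while the 4-residue window
    at the advancing edge keeps a mean propensity >= 1.0."""
    n = len(vals)
    regions: list[tuple[int, int]] = []
    above = vals > 1.0
    for i in range(n - nuc_win + 1):
        if int(above[i : i + nuc_win].sum()) >= nuc_count:
            if regions and i <= regions[-1][1] + 1:
                regions[-1] = (regions[-1][0], i + nuc_win - 1)
            else:
                regions.append((i, i + nuc_win - 1))
    extended = []
    for s, e in regions:
        while e + 1 < n:
            lo = max(0, e + 2 - _EXT_WIN)
            if vals[lo : e + 2].mean() >= 1.0:
                e += 1
            else:
                break
        while s > 0:
            hi = min(n, s - 1 + _EXT_WIN)
            if vals[s - 1 : hi].mean() >= 1.0:
                s -= 1
            else:
                break
        extended.append((s, e))
    # extension can create new overlaps; merge again
    merged: list[tuple[int, int]] = []
    for s, e in sorted(extended):
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def predict_secondary_structure(record: ProteinRecord) -> SecondaryStructureSummary:
    """Chou-Fasman secondary structure for a single sequence.

    Helices nucleate where 4 of 6 consecutive residues have P(H) > 1.00 and
    extend while the window-4 mean stays >= 1.00; strands analogously with
    3 of 5 residues of P(E) > 1.00. Where helix and strand assignments
    overlap, the state with the larger summed propensity over the overlap
    wins (strand on a tie — the screen targets beta-rich proteins and the
    published propensity tables make exact ties vanishingly rare).
    Sequences shorter than 6 residues return all-coil with ``too_short``
    set rather than failing, so degenerate decoys survive a proteome scan.
    """
    seq = record.sequence
    n = len(seq)
    if n < 6:
        return SecondaryStructureSummary(
            states="C" * n, frac_H=0.0, frac_E=0.0, frac_C=1.0, too_short=True
        )
    ph = _propensities(seq, CF_HELIX)
    pe = _propensities(seq, CF_STRAND)
    helix = _nucleate_and_extend(ph, _H_NUC_WIN, _H_NUC_COUNT)
    strand = _nucleate_and_extend(pe, _E_NUC_WIN, _E_NUC_COUNT)

    is_h = np.zeros(n, dtype=bool)
    is_e = np.zeros(n, dtype=bool)
    for s, e in helix:
        is_h[s : e + 1] = True
    for s, e in strand:
        is_e[s : e + 1] = True

    states = np.full(n, "C")
    states[is_h & ~is_e] = "H"
    states[is_e & ~is_h] = "E"
    both = is_h & is_e
    i = 0
    while i < n:
        if both[i]:
            j = i
            while j + 1 < n and both[j + 1]:
                j += 1
            winner = "E" if pe[i : j + 1].sum() >= ph[i : j + 1].sum() else "H"
            states[i : j + 1] = winner
            i = j + 1
        else:
            i += 1

    s = "".join(states)
    return SecondaryStructureSummary(
        states=s,
        frac_H=s.count("H") / n,
        frac_E=s.count("E") / n,
        frac_C=s.count("C") / n,
    )


# --- Sec signal peptide ---------------------------------------------------

SMALL_MINUS1 = frozenset("AGSCT")
SMALL_MINUS3 = frozenset("AGSCTVIL")


def detect_signal_peptide(
    record: ProteinRecord,
    h_window: int = 7,
    h_kd_min: float = 1.6,
    site_min: int = 10,
    site_max: int = 45,
) -> SignalPeptideCall:
    """Rule-based Sec signal-peptide call on the N-terminal 45 residues.

    Present iff all three hold:

    n-region
        at least one K/R within residues 1-7;
    h-region
        a stretch of >= ``h_window`` consecutive residues within residues
        4-25 whose mean Kyte-Doolittle value is >= ``h_kd_min``. The first
        qualifying window is refined by extending both edges while the
        per-residue value stays >= ``h_kd_min`` (within 4-25);
    c-region
        a cleavage site ``site_min``..``site_max`` residues in, at least 2
        residues past the h-region end, whose -1 residue is in {A,G,S,C,T}
        and -3 residue in {A,G,S,C,T,V,I,L} (von Heijne's small-residue
        rule). ``cleavage_after`` is the first qualifying position.

    Sequences shorter than 30 residues return absent with ``too_short``.
    Everything after residue 45 is ignored by construction.
    """
    seq = record.sequence[: site_max]
    if len(record.sequence) < 30:
        return SignalPeptideCall(False, None, None, 0.0, too_short=True)
    kd = [KYTE_DOOLITTLE.get(aa, 0.0) for aa in seq]

    n_ok = any(aa in "KR" for aa in seq[:7])

    h_region: tuple[int, int] | None = None
    h_lo, h_hi = 4, 25  # 1-based bounds of the allowed h-region
    for start in range(h_lo, h_hi - h_window + 2):  # 1-based window start
        window = kd[start - 1 : start - 1 + h_window]
        if len(window) < h_window:
            break
        if float(np.mean(window)) >= h_kd_min:
            s, e = start, start + h_window - 1
            while s - 1 >= h_lo and kd[s - 2] >= h_kd_min:
                s -= 1
            while e + 1 <= min(h_hi, len(seq)) and kd[e] >= h_kd_min:
                e += 1
            h_region = (s, e)
            break

    cleavage: int | None = None
    if n_ok and h_region is not None:
        for c in range(max(site_min, h_region[1] + 2), min(site_max, len(seq)) + 1):
            if c - 3 < 0:
                continue
            if seq[c - 1] in SMALL_MINUS1 and seq[c - 3] in SMALL_MINUS3:
                cleavage = c
                break

    present = n_ok and h_region is not None and cleavage is not None
    score = 0.0
    if h_region is not None:
        score = float(np.mean(kd[h_region[0] - 1 : h_region[1]]))
    return SignalPeptideCall(
        present=present,
        cleavage_after=cleavage if present else None,
        h_region=h_region,
        score=score,
    )


# --- Globularity ----------------------------------------------------------


def _centered_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges."""
    kernel = np.ones(window)
    sums = np.convolve(x, kernel, mode="same")
    counts = np.convolve(np.ones_like(x), kernel, mode="same")
    return sums / counts


def _runs(mask: np.ndarray) -> list[tuple[bool, int, int]]:
    """Maximal constant runs of a boolean array as (value, start, end)."""
    out = []
    i = 0
    while i < len(mask):
        j = i
        while j + 1 < len(mask) and mask[j + 1] == mask[i]:
            j += 1
        out.append((bool(mask[i]), i, j))
        i = j + 1
    return out


def assess_globularity(
    record: ProteinRecord,
    smooth_window: int = 15,
    min_domain_len: int = 40,
    coverage_min: float = 0.5,
    max_interruption: int = 6,
    max_interruption_rise: float = 1.0,
) -> GlobularityCall:
    """Disorder running-sum globularity detector.

    Each residue contributes its Russell/Linding disorder propensity minus
    the scale mean; the cumulative sum is smoothed with a centered
    ``smooth_window`` moving average, and maximal downhill stretches of the
    smoothed curve of at least ``min_domain_len`` residues are reported as
    globular domains. An uphill interruption of at most
    ``max_interruption`` steps rising by at most ``max_interruption_rise``
    (propensity-sum units) does not break a domain — ordered regions with
    an occasional polar turn would otherwise fragment, while sustained
    disorder still terminates the descent. The protein is called globular
    when domains cover at least ``coverage_min`` of the sequence.
    Degenerate lengths simply come back non-globular.
    """
    seq = record.sequence
    n = len(seq)
    if n < 2:
        return GlobularityCall(globular=False, domains=(), coverage=0.0)
    p = np.array([DISORDER.get(aa, DISORDER_MEAN) for aa in seq])
    s = np.cumsum(p - DISORDER_MEAN)
    s_smooth = _centered_mean(s, smooth_window)
    diffs = np.diff(s_smooth)
    runs = _runs(diffs < 0)

    # assemble downhill domains, bridging brief shallow uphill blips
    domains: list[tuple[int, int]] = []
    current: tuple[int, int] | None = None  # diff-index interval
    for idx, (is_down, i, j) in enumerate(runs):
        if is_down:
            if current is None:
                current = (i, j)
            else:
                current = (current[0], j)
        else:
            rise = float(diffs[i : j + 1].sum())
            length = j - i + 1
            bridgeable = (
                current is not None
                and length <= max_interruption
                and rise <= max_interruption_rise
                and idx + 1 < len(runs)  # must be followed by more descent
            )
            if not bridgeable and current is not None:
                domains.append(current)
                current = None
    if current is not None:
        domains.append(current)

    # diff interval [a, b] spans residues a .. b+1 (0-based)
    kept = [
        (a + 1, b + 2)  # 1-based inclusive residue interval
        for a, b in domains
        if (b - a + 2) >= min_domain_len
    ]
    coverage = sum(e - s0 + 1 for s0, e in kept) / n
    return GlobularityCall(
        globular=coverage >= coverage_min,
        domains=tuple(kept),
        coverage=coverage,
    )
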