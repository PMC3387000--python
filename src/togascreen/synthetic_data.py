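"""Seeded generators for synthetic proteomes and gene maps with planted truth.

The generators emulate the statistical structure the screen assumes, so
every stage is testable without downloads:

* **porins** — an N-terminal Sec signal built to the detector's own rules,
  a body of alternating beta-strand segments (V/I/L/Y/T/F/A-rich) and short
  polar turns (G/N/D/S-rich) mimicking a beta-barrel's architecture and the
  porin composition bias, and a C-terminal decamer carrying the anchoring
  signature (terminal F, hydrophobic odd positions);
* **decoys** — compact hydrophobic-core globular proteins, disordered
  E/S/P/G/K-rich chains, uniform-random sequences, and OmpA-like
  coiled-coil proteins (heptad repeats, hydrophobic C-tail but no terminal
  phenylalanine);
* **gene maps** — a genome of ~30 genes containing one secG-tyrS-ompA-ompB
  block, optionally with the ompB slot replaced by a non-homologous analog
  porin, mirroring the T. lettingae / T. africanus arrangement.

Every operation is a pure function of its arguments: the same seed gives
byte-identical output.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .seqio import GeneLocus, ProteinRecord, write_fasta, write_gene_table

#: Labels the generator can emit.
LABELS = (
    "porin",
    "analog_porin",
    "ompA_like",
    "decoy_globular",
    "decoy_disordered",
    "decoy_random",
)

DECOY_KINDS = ("globular", "disordered", "random", "ompA_like")


@dataclass
class PlantedTruth:
    """Ground truth for generated records.

    ``labels`` covers every generated record exactly once; porins (and
    analog porins) additionally carry their planted cleavage site and
    decamer.
    """

    labels: dict[str, str] = field(default_factory=dict)
    cleavage: dict[str, int] = field(default_factory=dict)
    decamers: dict[str, str] = field(default_factory=dict)

    def ids_with_label(self, label: str) -> list[str]:
        return sorted(i for i, l in self.labels.items() if l == label)

    def merge(self, other: "PlantedTruth") -> None:
        overlap = self.labels.keys() & other.labels.keys()
        if overlap:
            raise ValueError(f"duplicate truth ids: {sorted(overlap)}")
        self.labels.update(other.labels)
        self.cleavage.update(other.cleavage)
        self.decamers.update(other.decamers)


def _choices(rng: np.random.Generator, alphabet: str, weights, size: int) -> str:
    w = np.asarray(weights, dtype=float)
    return "".join(rng.choice(list(alphabet), size=size, p=w / w.sum()))


# Body segment alphabets. Strand segments carry the beta-favouring,
# membrane-facing residues; turn segments carry the small polar residues
# porins are enriched in. The 8 porin-depleted residues (R,C,E,H,I->low
# except I, M,P,W) are absent from the turn alphabet and only I appears in
# strands, so the composition bias emerges from the architecture itself.
_STRAND_ALPHA, _STRAND_W = "VILYTFA", (3.0, 2.0, 2.5, 1.5, 1.5, 1.0, 1.8)
_TURN_ALPHA, _TURN_W = "GNDSQKA", (3.0, 1.8, 2.2, 1.2, 0.6, 0.8, 0.4)

_H_ALPHA, _H_W = "LVIFA", (3.0, 2.0, 1.5, 1.0, 1.5)  # signal h-region
_ODD_ALPHA = "VALIF"  # hydrophobic face of the planted decamer
_EVEN_ALPHA, _EVEN_W = "SKGYANDQT", (1.5, 1.5, 1.0, 1.0, 1.0, 1.0, 1.0, 0.5, 0.5)


def _make_signal(rng: np.random.Generator) -> tuple[str, int]:
    """A Sec signal conforming to the detector's three rules.

    Returns the signal sequence and the 1-based cleavage site. Layout:
    Met, 2-3 basic residues (n-region), 8-11 strongly hydrophobic residues
    (h-region), then the A-Q-A cleavage cassette satisfying the (-3,-1)
    small-residue rule two residues past the h-region.
    """
    n_len = int(rng.integers(2, 4))
    h_len = int(rng.integers(8, 12))
    signal = (
        "M"
        + _choices(rng, "KR", (2.0, 1.0), n_len)
        + _choices(rng, _H_ALPHA, _H_W, h_len)
        + "AQA"
    )
    return signal, len(signal)


def _make_body(rng: np.random.Generator, body_len: int) -> str:
    segments = []
    total = 0
    while total < body_len:
        s_len = int(rng.integers(7, 12))
        segments.append(_choices(rng, _STRAND_ALPHA, _STRAND_W, s_len))
        t_len = int(rng.integers(3, 6))
        segments.append(_choices(rng, _TURN_ALPHA, _TURN_W, t_len))
        total += s_len + t_len
    return "".join(segments)[:body_len]


def _make_decamer(rng: np.random.Generator) -> str:
    """Decamer (N->C) with terminal F and hydrophobic positions 3,5,7,9."""
    positions = {}
    positions[1] = "F"
    for i in (3, 5, 7, 9):
        positions[i] = _choices(rng, _ODD_ALPHA, np.ones(len(_ODD_ALPHA)), 1)
    for i in (2, 4, 6, 8, 10):
        positions[i] = _choices(rng, _EVEN_ALPHA, _EVEN_W, 1)
    return "".join(positions[i] for i in range(10, 0, -1))


def make_porin(
    seed: int, length: int = 410, record_id: str | None = None
) -> tuple[ProteinRecord, PlantedTruth]:
    """A planted porin passing all five screening criteria by construction."""
    if length < 60:
        raise ValueError("porin length must be >= 60 to fit signal and decamer")
    rng = np.random.default_rng([seed, 101])
    signal, cleavage = _make_signal(rng)
    body = _make_body(rng, length - len(signal) - 10)
    decamer = _make_decamer(rng)
    rid = record_id or f"porin_s{seed}"
    record = ProteinRecord(id=rid, sequence=signal + body + decamer)
    truth = PlantedTruth(
        labels={rid: "porin"}, cleavage={rid: cleavage}, decamers={rid: decamer}
    )
    return record, truth


# Decoy composition weights (relative to nothing — they are the sampling
# distributions themselves).
_GLOB_ALPHA = "ACDEFGHIKLMNPQRSTVWY"

# Mixed alpha/beta fold for the globular decoy: amphipathic-helix segments,
# short buried strands, charged loops. The N-terminal cap uses the charged/
# polar subset — cytoplasmic proteins carry no hydrophobic export stretch
# at the N-terminus, which is exactly what distinguishes them from the
# secreted porins here.
_GCAP_ALPHA, _GCAP_W = "EAKQRSDNG", (2.0, 1.5, 2.0, 1.0, 1.0, 1.0, 1.0, 0.8, 0.7)
_GHELIX_ALPHA, _GHELIX_W = "EALKQRSD", (2.0, 2.0, 2.0, 2.0, 1.0, 1.0, 0.8, 1.0)
_GSTRAND_ALPHA, _GSTRAND_W = "IVLF", (1.5, 1.5, 1.5, 1.0)
_GLOOP_ALPHA, _GLOOP_W = "GDKNSE", (1.5, 1.0, 1.0, 1.0, 1.0, 1.0)

_DIS_ALPHA, _DIS_W = "ESPGKQADNTR", (2.0, 2.0, 1.5, 2.0, 2.0, 1.0, 0.5, 1.0, 0.5, 0.5, 0.5)

_HEPTAD_CORE, _HEPTAD_CORE_W = "LAVI", (2.0, 2.0, 1.0, 1.0)
_HEPTAD_OUT, _HEPTAD_OUT_W = "EKQRSNDAG", (2.5, 2.5, 1.0, 1.0, 0.8, 0.8, 1.0, 0.7, 0.3)


def _length(rng: np.random.Generator, mean: float, sd: float, lo: int = 60) -> int:
    return int(max(lo, round(rng.normal(mean, sd))))


def make_decoy(
    seed: int, kind: str, record_id: str | None = None
) -> tuple[ProteinRecord, PlantedTruth]:
    """A decoy of the given kind; see the module docstring for the designs."""
    if kind not in DECOY_KINDS:
        raise ValueError(f"unknown decoy kind {kind!r}")
    rng = np.random.default_rng([seed, 211 + DECOY_KINDS.index(kind)])

    if kind == "globular":
        n = _length(rng, 240, 60, lo=80)
        # N-terminal helix cap, then alternating helix / short strand / loop
        # segments: a compact cytoplasmic mixed alpha/beta architecture with
        # neither an export signal nor a porin-grade strand content.
        parts = ["M" + _choices(rng, _GCAP_ALPHA, _GCAP_W, int(rng.integers(25, 31)))]
        total = len(parts[0])
        while total < n:
            strand = _choices(rng, _GSTRAND_ALPHA, _GSTRAND_W, int(rng.integers(4, 6)))
            loop = _choices(rng, _GLOOP_ALPHA, _GLOOP_W, int(rng.integers(2, 4)))
            helix = _choices(rng, _GHELIX_ALPHA, _GHELIX_W, int(rng.integers(8, 15)))
            parts += [strand, loop, helix, _choices(rng, _GLOOP_ALPHA, _GLOOP_W, 2)]
            total += len(strand) + len(loop) + len(helix) + 2
        seq = "".join(parts)[: n - 1]
        seq += _choices(rng, "LVAIGK", np.ones(6), 1)  # no anchoring terminal F
        label = "decoy_globular"
    elif kind == "disordered":
        n = _length(rng, 220, 70)
        seq = _choices(rng, _DIS_ALPHA, _DIS_W, n)
        label = "decoy_disordered"
    elif kind == "random":
        n = _length(rng, 280, 90)
        seq = _choices(rng, _GLOB_ALPHA, np.ones(20), n)
        label = "decoy_random"
    else:  # ompA_like
        n = _length(rng, 430, 30, lo=350)
        heptads = []
        while sum(len(h) for h in heptads) < n - 20:
            h = list(_choices(rng, _HEPTAD_OUT, _HEPTAD_OUT_W, 7))
            h[0] = _choices(rng, _HEPTAD_CORE, _HEPTAD_CORE_W, 1)  # a position
            h[3] = _choices(rng, _HEPTAD_CORE, _HEPTAD_CORE_W, 1)  # d position
            heptads.append("".join(h))
        body = "".join(heptads)[: n - 20]
        tail = _choices(rng, "LVIAF", np.ones(5), 19)
        tail += _choices(rng, "LVAI", np.ones(4), 1)  # hydrophobic tail, no terminal F
        seq = body + tail
        label = "ompA_like"

    rid = record_id or f"{label}_s{seed}"
    record = ProteinRecord(id=rid, sequence=seq)
    return record, PlantedTruth(labels={rid: label})


def make_reference_set(seed: int, n: int = 5) -> list[ProteinRecord]:
    """Reference porins for the relative beta-range criterion."""
    refs = []
    for i in range(n):
        length = 390 + 10 * (i % 5)
        rec, _ = make_porin(seed * 1000 + i, length=length, record_id=f"ref_porin_{i}")
        refs.append(rec)
    return refs


def make_proteome(
    n: int, k_porins: int, seed: int
) -> tuple[list[ProteinRecord], PlantedTruth]:
    """A shuffled proteome of ``k_porins`` planted porins and ``n - k`` decoys.

    Decoy kinds cycle through globular / disordered / random / OmpA-like in
    equal proportion. Record ids are positional (``P0001``...), assigned
    after a seeded shuffle, so the label table is the only route back to
    the truth.
    """
    if not 0 <= k_porins <= n:
        raise ValueError(f"need 0 <= k_porins <= n, got k={k_porins}, n={n}")
    rng = np.random.default_rng([seed, 3])
    made: list[tuple[ProteinRecord, PlantedTruth]] = []
    for i in range(k_porins):
        length = int(rng.integers(380, 441))
        made.append(make_porin(seed * 100_000 + i, length=length))
    for j in range(n - k_porins):
        kind = DECOY_KINDS[j % len(DECOY_KINDS)]
        made.append(make_decoy(seed * 100_000 + k_porins + j, kind))

    order = rng.permutation(len(made))
    records: list[ProteinRecord] = []
    truth = PlantedTruth()
    for new_idx, old_idx in enumerate(order):
        rec, t = made[old_idx]
        rid = f"P{new_idx + 1:04d}"
        records.append(ProteinRecord(id=rid, sequence=rec.sequence))
        old_id = rec.id
        truth.labels[rid] = t.labels[old_id]
        if old_id in t.cleavage:
            truth.cleavage[rid] = t.cleavage[old_id]
            truth.decamers[rid] = t.decamers[old_id]
    return records, truth


def _make_analog_porin(
    seed: int, record_id: str
) -> tuple[ProteinRecord, PlantedTruth]:
    """A non-homologous analog porin for the ompB syntenic slot.

    Signal peptide and anchoring decamer as in a planted porin, but a
    uniform-random body: the protein keeps the porin hallmarks the analog
    argument rests on (export signal, size, C-terminal signature) while
    sharing no recognisable sequence similarity with the porin family —
    like the putative analogs, it also loses the globularity criterion.
    """
    rng = np.random.default_rng([seed, 977])
    signal, cleavage = _make_signal(rng)
    length = int(rng.integers(340, 381))
    body = _choices(rng, _GLOB_ALPHA, np.ones(20), length - len(signal) - 10)
    decamer = _make_decamer(rng)
    record = ProteinRecord(id=record_id, sequence=signal + body + decamer)
    truth = PlantedTruth(
        labels={record_id: "analog_porin"},
        cleavage={record_id: cleavage},
        decamers={record_id: decamer},
    )
    return record, truth


def make_genome_map(
    seed: int, with_analog: bool = False
) -> tuple[list[GeneLocus], list[ProteinRecord], PlantedTruth]:
    """A ~30-gene genome containing one secG-tyrS-ompA-ompB block.

    With ``with_analog`` the ompB slot carries an analog porin instead: a
    gene outside every pattern family whose product nonetheless passes the
    relaxed C-terminus rule and at least three criteria. Proteins are
    returned for the block genes plus, in analog mode, a porin-family
    representative for identity checks.
    """
    rng = np.random.default_rng([seed, 13])
    genome_id = f"G{seed:04d}"
    n_genes = 30
    block_start = int(rng.integers(2, n_genes - 6))

    loci: list[GeneLocus] = []
    records: list[ProteinRecord] = []
    truth = PlantedTruth()

    pattern = ("secG", "tyrS", "ompA", "ompB")
    for i in range(n_genes):
        tag = f"{genome_id}_{1000 + i}"
        offset = i - block_start
        if 0 <= offset < 4:
            if offset == 3 and with_analog:
                family = f"hyp_{genome_id}"
            else:
                family = pattern[offset]
            strand = "+"
        else:
            family = f"fam{seed % 997:03d}_{i:03d}"
            strand = "+" if rng.random() < 0.5 else "-"
        loci.append(
            GeneLocus(
                genome_id=genome_id,
                locus_tag=tag,
                ordinal=i,
                strand=strand,
                family=family,
            )
        )

    block_tags = [loci[block_start + k].locus_tag for k in range(4)]

    for kind, tag in zip(("random", "random"), block_tags[:2]):
        rec, t = make_decoy(seed * 17 + len(records), kind, record_id=tag)
        records.append(rec)
        truth.merge(t)
    ompa_rec, ompa_truth = make_decoy(seed * 17 + 7, "ompA_like", record_id=block_tags[2])
    records.append(ompa_rec)
    truth.merge(ompa_truth)

    if with_analog:
        analog_rec, analog_truth = _make_analog_porin(seed, block_tags[3])
        records.append(analog_rec)
        truth.merge(analog_truth)
        rep, rep_truth = make_porin(seed * 31 + 5, record_id=f"{genome_id}_ompB_rep")
        records.append(rep)
        truth.merge(rep_truth)
    else:
        porin_rec, porin_truth = make_porin(seed * 31 + 5, record_id=block_tags[3])
        records.append(porin_rec)
        truth.merge(porin_truth)

    return loci, records, truth


def write_truth(truth: PlantedTruth, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("id\tlabel\tcleavage_after\tdecamer\n")
        for rid in sorted(truth.labels):
            cleav = truth.cleavage.get(rid, "")
            dec = truth.decamers.get(rid, "")
            fh.write(f"{rid}\t{truth.labels[rid]}\t{cleav}\t{dec}\n")


def write_simulation(
    outdir: str | os.PathLike,
    n: int,
    k_porins: int,
    seed: int,
    with_analog: bool = False,
) -> dict[str, str]:
    """Emit proteome.fasta, genes.tsv and truth.tsv for a full simulation.

    The proteome holds ``n`` records plus the genome-map proteins, so both
    the screening and the synteny command lines can run end-to-end on the
    same directory.
    """
    os.makedirs(outdir, exist_ok=True)
    records, truth = make_proteome(n, k_porins, seed)
    loci, map_records, map_truth = make_genome_map(seed, with_analog=with_analog)
    truth.merge(map_truth)

    paths = {
        "proteome": os.path.join(outdir, "proteome.fasta"),
        "genes": os.path.join(outdir, "genes.tsv"),
        "truth": os.path.join(outdir, "truth.tsv"),
        "references": os.path.join(outdir, "references.fasta"),
    }
    write_fasta(records + map_records, paths["proteome"])
    write_gene_table(loci, paths["genes"])
    write_truth(truth, paths["truth"])
    write_fasta(make_reference_set(seed + 500_009), paths["references"])
    return paths
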