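"""Reading and writing the flat-file formats the screen touches.

Three formats: multi-record protein FASTA (via Biopython), tab-delimited
gene tables carrying per-genome gene order for synteny analysis, and the
tab-delimited screening report whose column layout mirrors the candidate
table of the screen (one row per protein, one column per criterion).

Sequences are validated on ingest: the strict default alphabet is the 20
canonical one-letter codes; ``allow_x=True`` additionally admits ``X``,
which downstream statistics exclude from per-residue denominators and
treat as non-hydrophobic.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._tables import CANONICAL_RESIDUES


class ParseError(ValueError):
    """Malformed input file (bad residue, duplicate locus, bad strand...)."""


_CANONICAL = set(CANONICAL_RESIDUES)


@dataclass(frozen=True)
class ProteinRecord:
    """An identified amino-acid sequence; the unit everything scores.

    ``id`` is unique within a record set and contains no whitespace;
    ``sequence`` is uppercase over the canonical alphabet (plus ``X`` when
    explicitly allowed).
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ParseError(f"record id {self.id!r} is empty or has whitespace")
        if not self.sequence:
            raise ParseError(f"record {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneLocus:
    """One gene in a genome's gene-order table.

    ``ordinal`` is the 0-based position along the replicon — the synteny
    logic depends only on gene order and orientation, never on base-pair
    coordinates. ``family`` is a homology-family label (possibly empty,
    meaning unassigned).
    """

    genome_id: str
    locus_tag: str
    ordinal: int
    strand: str
    family: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ParseError(
                f"{self.genome_id}/{self.locus_tag}: strand must be '+' or '-', "
                f"got {self.strand!r}"
            )
        if self.ordinal < 0:
            raise ParseError(f"{self.locus_tag}: ordinal must be >= 0")


def _validate_sequence(seq: str, record_id: str, allow_x: bool) -> str:
    seq = seq.upper()
    alphabet = _CANONICAL | {"X"} if allow_x else _CANONICAL
    for pos, ch in enumerate(seq, start=1):
        if ch not in alphabet:
            raise ParseError(
                f"record {record_id!r}: illegal residue {ch!r} at position {pos}"
            )
    return seq


def read_fasta(path: str | os.PathLike, allow_x: bool = False) -> list[ProteinRecord]:
    """Parse a protein FASTA file into validated records.

    Order is preserved, one record per header; wrapped lines are joined and
    sequences uppercased. Raises :class:`ParseError` on a missing/empty file
    or on any residue outside the configured alphabet (the error names the
    record and 1-based position).
    """
    if not os.path.exists(path):
        raise ParseError(f"no such file: {path}")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = _validate_sequence(str(rec.seq), rec.id, allow_x)
        records.append(ProteinRecord(id=rec.id, sequence=seq, description=rec.description))
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | os.PathLike) -> None:
    """Write records as wrapped FASTA; inverse of :func:`read_fasta`."""
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(seqrecords, str(path), "fasta")


_GENE_COLUMNS = ["genome_id", "locus_tag", "ordinal", "strand", "family"]


def read_gene_table(path: str | os.PathLike) -> list[GeneLocus]:
    """Parse a tab-delimited gene table into loci grouped by genome.

    Expected header: ``genome_id  locus_tag  ordinal  strand  family``
    (family may be empty). Output is grouped by genome and sorted by ordinal
    within each genome. Duplicate (genome, locus_tag) pairs, duplicate
    ordinals within a genome, and strands outside {+,-} are rejected.
    """
    if not os.path.exists(path):
        raise ParseError(f"no such file: {path}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _GENE_COLUMNS:
            raise ParseError(
                f"{path}: expected header {_GENE_COLUMNS}, got {header}"
            )
        loci: list[GeneLocus] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno}: expected 5 columns")
            family = parts[4] if len(parts) > 4 else ""
            try:
                ordinal = int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad ordinal {parts[2]!r}") from exc
            loci.append(
                GeneLocus(
                    genome_id=parts[0],
                    locus_tag=parts[1],
                    ordinal=ordinal,
                    strand=parts[3],
                    family=family,
                )
            )
    seen_tags: set[tuple[str, str]] = set()
    seen_ordinals: set[tuple[str, int]] = set()
    for locus in loci:
        tag = (locus.genome_id, locus.locus_tag)
        if tag in seen_tags:
            raise ParseError(f"duplicate locus {locus.locus_tag} in {locus.genome_id}")
        seen_tags.add(tag)
        ordkey = (locus.genome_id, locus.ordinal)
        if ordkey in seen_ordinals:
            raise ParseError(
                f"duplicate ordinal {locus.ordinal} in genome {locus.genome_id}"
            )
        seen_ordinals.add(ordkey)
    loci.sort(key=lambda l: (l.genome_id, l.ordinal))
    return loci


def write_gene_table(loci: Iterable[GeneLocus], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_GENE_COLUMNS) + "\n")
        for l in sorted(loci, key=lambda x: (x.genome_id, x.ordinal)):
            fh.write(f"{l.genome_id}\t{l.locus_tag}\t{l.ordinal}\t{l.strand}\t{l.family}\n")


REPORT_COLUMNS = [
    "id",
    "mw_kda",
    "signal",
    "beta_pct",
    "globular",
    "cterm",
    "n_criteria",
    "candidate",
]


def _flag(x: bool) -> str:
    return "+" if x else "-"


def write_report(results, path: str | os.PathLike) -> None:
    """Write screening results as a tab-delimited candidate report.

    ``results`` is the output of ``porin_screen.screen_proteome`` — a list of
    ``(ProteinRecord, CriterionVector)`` pairs. One row per protein with
    molecular weight in kDa (2 decimals), +/- flags for signal peptide,
    globularity and the C-terminal signature, the beta-strand content as a
    percentage, the number of criteria met and the candidate call.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for record, vector in results:
            fh.write(
                "\t".join(
                    [
                        record.id,
                        f"{vector.mw_kda:.2f}",
                        _flag(vector.signal_ok),
                        f"{vector.beta_frac * 100:.2f}",
                        _flag(vector.globular_ok),
                        _flag(vector.cterm_ok),
                        str(vector.n_true),
                        _flag(vector.candidate),
                    ]
                )
                + "\n"
            )


def read_report(path: str | os.PathLike) -> list[dict]:
    """Re-parse a written report; used for round-trip checks and tooling."""
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != REPORT_COLUMNS:
            raise ParseError(f"{path}: unexpected report header {header}")
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            out.append(
                {
                    "id": parts[0],
                    "mw_kda": float(parts[1]),
                    "signal": parts[2] == "+",
                    "beta_pct": float(parts[3]),
                    "globular": parts[4] == "+",
                    "cterm": parts[5] == "+",
                    "n_criteria": int(parts[6]),
                    "candidate": parts[7] == "+",
                }
            )
    return out
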