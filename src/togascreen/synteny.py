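"""Conserved gene-order detection and analog flagging.

The biological argument: the genes ``secG-tyrS-ompA-ompB`` form a tight
syntenic block across Thermotogales genomes. A genome whose block carries
an unrelated gene in the terminal (ompB) slot is a candidate for an
*analog* porin — same genomic context and porin characteristics, no
recognisable homology.

Family grouping at desk scale uses global pairwise alignment identity with
single-linkage clustering (profile search against reference databases is
out of scope); gene tables may alternatively carry curated family labels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .porin_screen import CriterionVector
from .seqio import GeneLocus, ProteinRecord

DEFAULT_PATTERN = ("secG", "tyrS", "ompA", "ompB")


@dataclass(frozen=True)
class AlignmentResult:
    """A global alignment: score, gapped pair, and column identity."""

    score: int
    aligned_a: str
    aligned_b: str
    identity: float


@dataclass(frozen=True)
class SyntenyBlock:
    """A run of consecutive genes matching the pattern in one genome.

    ``analog_slot`` is set when every slot but the last matches and the
    last slot's gene belongs to no pattern family.
    """

    genome_id: str
    loci: tuple[GeneLocus, ...]
    same_strand: bool
    analog_slot: GeneLocus | None = None


def _aligner(gap_open: int, gap_extend: int) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # a gap of length k costs gap_open + (k-1) * gap_extend
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def global_align(
    a: ProteinRecord,
    b: ProteinRecord,
    gap_open: int = 11,
    gap_extend: int = 1,
) -> AlignmentResult:
    """Optimal global alignment under BLOSUM62 with affine gaps.

    A gap of length k costs ``gap_open + (k-1) * gap_extend``; terminal
    gaps are penalised like internal ones. Identity is the fraction of
    alignment columns in which both sequences carry the same residue
    (gap columns count toward the denominator). Among co-optimal
    alignments one is reported deterministically; the score is unique.
    """
    if not a.sequence or not b.sequence:
        raise ValueError("global_align requires two non-empty sequences")
    aligner = _aligner(gap_open, gap_extend)
    alignments = aligner.align(a.sequence, b.sequence)
    aln = alignments[0]
    ga, gb = str(aln[0]), str(aln[1])
    matches = sum(x == y and x != "-" for x, y in zip(ga, gb))
    return AlignmentResult(
        score=int(aln.score),
        aligned_a=ga,
        aligned_b=gb,
        identity=matches / len(ga),
    )


def cluster_families(
    records: Sequence[ProteinRecord],
    identity_threshold: float = 0.30,
    gap_open: int = 11,
    gap_extend: int = 1,
) -> dict[str, str]:
    """Single-linkage clustering of proteins on global-alignment identity.

    Two proteins join the same family when a chain of pairwise identities
    >= ``identity_threshold`` connects them. Each family is named after its
    lexicographically smallest member id, making labels independent of
    input order.
    """
    if not records:
        raise ValueError("cluster_families requires at least one record")
    ids = sorted(r.id for r in records)
    by_id = {r.id: r for r in records}
    parent = {i: i for i in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for ia, ib in itertools.combinations(ids, 2):
        if find(ia) == find(ib):
            continue
        result = global_align(by_id[ia], by_id[ib], gap_open, gap_extend)
        if result.identity >= identity_threshold:
            ra, rb = find(ia), find(ib)
            # smaller root name wins so labels are canonical
            if ra < rb:
                parent[rb] = ra
            else:
                parent[ra] = rb
    return {i: find(i) for i in ids}


def _group_by_genome(loci: Sequence[GeneLocus]) -> dict[str, list[GeneLocus]]:
    genomes: dict[str, list[GeneLocus]] = {}
    for locus in loci:
        genomes.setdefault(locus.genome_id, []).append(locus)
    for g in genomes.values():
        g.sort(key=lambda l: l.ordinal)
    return genomes


def find_syntenic_blocks(
    gene_tables: Sequence[GeneLocus],
    pattern: Sequence[str] = DEFAULT_PATTERN,
    max_gap: int = 0,
) -> list[SyntenyBlock]:
    """Find runs of consecutive genes matching the family pattern.

    A window of ``len(pattern)`` loci with strictly increasing ordinals
    (at most ``max_gap`` intervening genes between neighbours) matches
    when all loci lie on the '+' strand and families equal the pattern in
    order, or all lie on the '-' strand and families equal the exact
    reverse (the same physical gene order read from the other strand).
    Mixed-strand runs never match.

    A window matching all but the last pattern slot, where the gene in
    that slot belongs to *no* pattern family, is reported with
    ``analog_slot`` set to that gene.
    """
    pattern = tuple(pattern)
    if len(pattern) < 2:
        raise ValueError("pattern must have at least two family labels")
    if any(not p for p in pattern):
        raise ValueError("pattern contains an empty family label")
    pattern_set = set(pattern)
    k = len(pattern)
    blocks: list[SyntenyBlock] = []

    for genome_id, loci in sorted(_group_by_genome(gene_tables).items()):
        for start in range(len(loci) - k + 1):
            window = loci[start : start + k]
            gaps_ok = all(
                0 < window[i + 1].ordinal - window[i].ordinal <= max_gap + 1
                for i in range(k - 1)
            )
            if not gaps_ok:
                continue
            strands = {l.strand for l in window}
            if len(strands) != 1:
                continue
            forward = strands == {"+"}
            families = tuple(l.family for l in window)
            want = pattern if forward else tuple(reversed(pattern))
            # index of the terminal pattern slot within the window
            slot_idx = k - 1 if forward else 0
            if families == want:
                blocks.append(
                    SyntenyBlock(
                        genome_id=genome_id,
                        loci=tuple(window),
                        same_strand=True,
                        analog_slot=None,
                    )
                )
            else:
                body_idx = [i for i in range(k) if i != slot_idx]
                body_match = all(families[i] == want[i] for i in body_idx)
                slot_gene = window[slot_idx]
                if body_match and slot_gene.family not in pattern_set:
                    blocks.append(
                        SyntenyBlock(
                            genome_id=genome_id,
                            loci=tuple(window),
                            same_strand=True,
                            analog_slot=slot_gene,
                        )
                    )
    return blocks


def flag_analogs(
    blocks: Sequence[SyntenyBlock],
    screen: Mapping[str, CriterionVector],
) -> list[tuple[GeneLocus, str]]:
    """Judge each analog-slot gene with the porin screen.

    ``screen`` maps protein/locus ids to their criterion vectors. Verdict
    is ``"putative analog porin"`` when the slot protein carries the
    C-terminal anchoring signature and meets at least three criteria,
    otherwise ``"unresolved"``. A slot without a screening result is an
    error — the caller must screen every analog candidate.
    """
    out: list[tuple[GeneLocus, str]] = []
    for block in blocks:
        slot = block.analog_slot
        if slot is None:
            continue
        if slot.locus_tag not in screen:
            raise KeyError(f"no screening result for analog slot {slot.locus_tag}")
        vec = screen[slot.locus_tag]
        verdict = (
            "putative analog porin"
            if vec.cterm_ok and vec.n_true >= 3
            else "unresolved"
        )
        out.append((slot, verdict))
    return out
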