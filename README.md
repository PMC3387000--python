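# togascreen

Sequence-based screening for outer-membrane **porin candidates** in
bacterial proteomes, built around the biology of the Thermotogales
"toga" — the loose outer sheath whose major channel protein (a ~42 kDa
trimeric β-barrel porin) long lacked a gene assignment. Identifying such
a gene from sequence alone is a needle-in-a-proteome problem: porins
share almost no sequence similarity across species, but they do share
*physicochemical* hallmarks. `togascreen` turns those hallmarks into a
tested, reusable pipeline for genome annotators and cell-envelope
researchers.

## What it computes

For every protein, five boolean criteria; a protein meeting **≥ 3** is a
candidate and one meeting all **5** is a strong candidate:

1. **size** — average MW (ProtParam convention) in 35–50 kDa;
2. **signal** — a rule-based Sec signal peptide (n/h/c regions, (−3,−1)
   small-residue cleavage rule);
3. **β content** — Chou-Fasman strand fraction inside the range of a
   reference porin set *evaluated by the same predictor* (± 0.05);
4. **globularity** — Russell/Linding disorder running-sum detector
   (smoothed downhill domains ≥ 40 residues covering ≥ 50%);
5. **C-terminal anchoring signature** — terminal phenylalanine plus
   hydrophobic residues at positions 3, 5, 7, 9 of the last decamer
   (positions counted from the C-terminus; *relaxed* mode requires 3 of
   the 4, *strict* all 4).

It also scores the classic porin **composition bias** (low
R,C,E,H,I,M,P,W; high A,G,N,D,L vs a Swiss-Prot background), detects the
conserved **secG–tyrS–ompA–ompB synteny block** in gene-order tables, and
flags **analog porins**: genes occupying the ompB slot with porin
characteristics but no recognisable homology (global BLOSUM62 alignment
identity below the family-clustering threshold). A seeded synthetic-data
module generates proteomes and gene maps with planted ground truth so the
whole pipeline is testable offline.

## Worked example

Simulate a 50-protein proteome with 5 planted porins plus a genome map
whose ompB slot carries an analog, then screen it:

```bash
$ togascreen simulate --n 50 --k 5 --seed 11 --with-analog -o demo
$ togascreen scan --fasta demo/proteome.fasta \
      --references demo/references.fasta -o demo/report.tsv
screened 55 proteins, 7 candidates -> demo/report.tsv
$ head -4 demo/report.tsv
id      mw_kda  signal  beta_pct        globular        cterm   n_criteria      candidate
P0016   42.07   +       93.91   +       +       5       +
P0043   41.46   +       92.93   +       +       5       +
G0011_ompB_rep  43.71   +       96.83   +       +       5       +
```

The report mirrors the screen's criteria column-for-column: molecular
weight in kDa, +/− calls for signal peptide, globularity and the
C-terminal signature, the β-strand percentage, criteria met, and the
candidate call, ranked by criteria met and proximity to 42 kDa. The
planted porins (here `P0016`, `P0043`, …, cross-checked via
`demo/truth.tsv`) surface as strong candidates.

The synteny command finds the planted block and judges the analog slot:

```bash
$ togascreen synteny --genes demo/genes.tsv --proteins demo/proteome.fasta \
      --references demo/references.fasta -o demo/blocks.tsv
$ cat demo/blocks.tsv
genome_id  start_tag   end_tag     families                  analog_slot  verdict
G0011      G0011_1004  G0011_1007  secG,tyrS,ompA,hyp_G0011  G0011_1007   putative analog porin
```

`G0011_1007` sits where ompB should be, belongs to no pattern family,
yet carries an export signal, porin-range size and the anchoring
signature — the synteny-plus-characteristics argument for an analog
porin, exactly the situation of the two Thermotogales species whose toga
porin gene is not a recognisable homolog.

Library use is one import away:

```python
from togascreen import make_porin, make_reference_set, evaluate_candidate
porin, truth = make_porin(seed=1)
vec = evaluate_candidate(porin, make_reference_set(999))
vec.n_true, vec.candidate, vec.strong   # (5, True, True)
```

## Layout

- `src/togascreen/seqio.py` — FASTA, gene-table and report I/O
- `src/togascreen/physchem.py` — masses, composition, hydropathy
- `src/togascreen/structure_pred.py` — Chou-Fasman, signal, globularity
- `src/togascreen/porin_screen.py` — the five criteria and the caller
- `src/togascreen/synteny.py` — alignment, clustering, blocks, analogs
- `src/togascreen/synthetic_data.py` — seeded generators with planted truth
- `docs/methods.md` — models, parameters, defaults, and limitations
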