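# alnmark

Annotate pairwise and multiple sequence alignments with genetic variants,
post-translational modifications and interval tracks — and see where they
land across species.

## The problem

Every position of a protein or genome accumulates its own facts: missense
variants with clinical significance and allele frequencies, PTMs such as
ubiquitination (`K2563-ub`), protein domains, CRISPR sgRNA targets. These
facts are recorded in *native* coordinates — the 1-based residue or
nucleotide position of one sequence, the numbering HGVS-style tokens use
(`p.C4957Y`, `c.88C>G`). An alignment inserts gaps, so native positions and
alignment columns diverge, and homologous positions in different species
carry *different* native numbers: a human RYR2 substitution at residue 4957
and its mouse counterpart at residue 4956 are the same site once aligned.
Variants like these, co-located in one alignment column across species, are
**orthologous variants (OrthoVars)** — and finding them is a pure exercise
in gapped↔ungapped coordinate mapping.

`alnmark` is a scriptable toolkit for exactly this bookkeeping:

- **FASTA alignment I/O** with normalisation, identity parsing
  (UniProt / NCBI RefSeq / Ensembl accessions → database URLs) and a
  per-column majority **consensus** row;
- **coordinate maps** between 1-based ungapped positions and alignment
  columns (gap columns map to a `GAP` sentinel, never to an integer);
- a documented **JSON annotation schema** (variants, modifications,
  regions; positions in native coordinates) with validation, HGVS-like
  token parsing and reference-letter consistency warnings;
- **column projection and OrthoVar detection**: annotations are bucketed
  per column, and any column holding variants from ≥ 2 distinct sequences
  is reported as an orthologous group;
- **rendering**: a self-contained interactive HTML document (13 colour
  schemes, region track, asterisk notification row, circled annotated
  cells with CSS-only hover pop-ups, consensus row, hyperlinked labels)
  and a static SVG figure rasterizable to PNG, both windowed over columns;
- a deterministic **synthetic fixture generator** that plants co-located
  variant pairs with known ground truth;
- a thin **CLI** (`alnmark render|find|orthovars|consensus|validate|toydata|schemes`).

## The core mapping

For sequence *s* with gapped letters *L*, the position map is built in one
scan: `col_of_pos[p]` is the column of the *p*-th non-gap letter, and
`pos_of_col[c]` is its inverse on non-gap columns (`GAP` elsewhere), so
`pos_of_col ∘ col_of_pos = id` on `1..ungapped_length`. A variant recorded
at native position *p* on sequence *s* is drawn at column `col_of_pos[p]`;
two variants on distinct sequences whose columns coincide form an
orthologous group. The consensus letter of column *c* is
`argmax` over the non-gap tally of that column, ties broken alphabetically,
with `-` only for all-gap columns.

## Worked example

```python
import json
from alnmark import read_fasta, load_annotations, index_by_column, ortho_groups

# mouse lacks one residue upstream, so native positions 4 vs 3 share a column
aln = read_fasta(">human RYR2-like\nMAKCV\n>mouse Ryr2-like\nM-KCV\n")
aset = load_annotations(json.dumps({"variants": [
    {"sequence": 0, "position": 4, "token": "p.C4Y", "source": "ClinVar"},
    {"sequence": 1, "position": 3, "token": "p.C3Y", "source": "MGI"},
]}), aln)
for g in ortho_groups(index_by_column(aset, aln)):
    print(g.column, [(v.seq_index, v.token) for v in g.members])
```

prints

```
4 [(0, 'p.C4Y'), (1, 'p.C3Y')]
```

— one orthologous group at column 4: the two substitutions hit the same
aligned site although their native positions differ. The `examples/`
directory holds one short script per capability (consensus and identities,
position search, OrthoVar detection, HTML/SVG/PNG rendering, synthetic
fixtures), each printing what it computes.

From the shell:

```
alnmark toydata --out-prefix toy --seed 3
alnmark orthovars --fasta toy.fasta --annotations toy.json
alnmark render --fasta toy.fasta --annotations toy.json --out toy.html
alnmark find --fasta toy.fasta --sequence "Mus" --pos 4
```

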