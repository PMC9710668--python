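# Methods

## Model of the data

An **alignment** is an ordered, rectangular set of gapped sequence records
over `A–Z` plus `-`; input order is preserved because row order is a
display property users control. On ingest, sequences are uppercased and
`.` gaps normalised to `-` (alignment FASTA dialects differ on both);
lowercase carries no masking semantics here. A single sequence is a legal,
degenerate alignment.

**Coordinates** are 1-based and inclusive everywhere a user sees them,
matching HGVS-style tokens (`p.C4957Y` = the 4957th residue). Per sequence,
`col_of_pos` maps residue position → column and `pos_of_col` maps column →
residue position or the `GAP` sentinel. The sentinel is a distinguished
object rather than 0/−1 so that accidental arithmetic on a gap position
fails loudly instead of silently shifting results. Strands are not
interpreted; alignments are taken as written.

**Annotations** use native (ungapped) coordinates of their sequence. This
is the only choice under which a human variant at residue 4957 and a mouse
variant at residue 4956 can be recognised as the same aligned site: each is
recorded in its own protein's numbering and the gap structure reconciles
them. Global regions are the exception — they live in column space, for
intervals that describe the alignment itself. The JSON schema
(`src/alnmark/schema/annotations-v1.json`) is this package's own,
versioned; unknown keys on an annotation are preserved as free-form
attributes and surfaced in pop-ups (allele frequency, clinical
significance, …).

## Procedures

**Consensus.** Per column, tally non-gap letters; emit the majority
residue, ties broken alphabetically; emit `-` only for an all-gap column.
Alphabetical tie-breaking is arbitrary but deterministic and stable under
re-rendering; gaps never win a contested column because a residue is the
more informative display. No plurality threshold is applied.

**Token parsing.** Two substitution forms are parsed: `p.<AA><int><AA>`
(20 amino-acid codes plus `X` and `*`) and `c.<int><base>><base>`
(ACGTU), with interior whitespace tolerated (`p. C4957Y`). Everything
else — indels, delins, frameshifts — is deliberately kept as display-only
text: a full HGVS grammar buys little for co-location and costs much in
edge cases. A parseable token must agree with the annotation's `position`
field (an internal contradiction is a validation error), but a reference
letter that mismatches the aligned sequence only warns, since isoform and
version drift between annotation sources and alignments is routine.

**Column projection and OrthoVar grouping.** Variants and modifications
are mapped through their sequence's position map into per-column buckets,
ordered by (sequence index, variants before modifications, insertion
order) so serialisations are byte-stable. A column whose bucket holds
variants from at least two distinct sequences yields one orthologous
group containing all variants of that column; modifications never join a
group (cross-kind co-location is still visible in the shared bucket), and
multiple variants on one sequence never form a group alone.

**Selectors.** A sequence may be addressed by 0-based index, exact label
or header, or a case-insensitive unique label prefix; ambiguity is an
error listing the candidates. Out-of-range positions error (reporting the
ungapped length) rather than clamp — silent clamping would misattribute
annotations.

## Rendering

Both emitters consume one resolved plan (scheme, inclusive column window,
excluded rows, cell size, consensus toggle, sanitize flag) and share one
layout pass. Defaults: 18 px cells, 120 px label gutter, 14 px track
lanes, 500-column pagination chunks — legible output with bounded file
size. Region intervals that overlap are stacked into lanes by greedy
interval colouring on start column.

The HTML document is fully self-contained: inline CSS, no scripts, no
network fetches. Pop-ups are CSS `:hover` blocks, so the original
live-widget interactions (drag scrolling, click-to-hide) map to static
equivalents — the `--window` and `--exclude` options and, for documents
wider than the chunk size, consecutive window blocks in one file (the
static analogue of render-as-you-scroll). Annotated cells are drawn round,
plain cells square; modified columns get a red asterisk in the
notification row; row labels hyperlink via the parsed sequence identity.
Notes may carry raw HTML for rich pop-ups; `sanitize` strips all tags for
untrusted inputs. Both emitters are byte-deterministic — no timestamps, no
generated ids — so repeated runs are diffable.

The 13 colour schemes are the classic palette family of Jalview-style
viewers (clustal, clustalx, zappo, taylor, hydrophobicity, helix-, strand-
and turn-propensity, buried-index, cinema, lesk, mae, nucleotide). Each is
total over its family alphabet plus `-`; letters outside the alphabet
(e.g. ambiguity codes) render white. Propensity/burial palettes are
standard colour ramps over the usual scales; cells encode the residue, not
a measurement, so palette fidelity is aesthetic rather than quantitative.

SVG geometry is contractual: width = gutter + window·cell, height = track
band (one lane per stacked region row + the notification row, 14 px each)
+ one cell row per visible sequence (+ consensus when enabled). PNG export
parses the package's own SVG — a fixed vocabulary of rects, circles, text
and anchors — and draws it with Pillow at `dpi/96` scale, so pixel
dimensions are the SVG dimensions scaled and rounded.

## Synthetic fixtures

The generator emulates the one structure the method needs: sequences that
are residue-identical but gap-divergent. A random ancestral sequence
(uniform over the 20 amino acids, or ACGT in nucleotide mode) is copied
into every row; each row receives the same *number* of inserted gap
columns, `G = round(gap_rate/(1−gap_rate)·L)`, at row-specific random
positions. Equal gap counts keep the alignment rectangular without
substituting residues, so every row's ungapped length stays exactly `L`
and planted-position bookkeeping is exact. Variant pairs are planted by
choosing a column where two rows both carry residues and recomputing each
row's native position through its own gap pattern; lone variants get
columns of their own. Tokens are built from the actual residue at the
planted position, so the consistency checker stays silent. Everything
derives from one `random.Random(seed)` stream: same spec, same bytes.

What the generator does **not** emulate: substitution processes, indel
length distributions, phylogenetic correlation, or any realistic sequence
evolution. Passing the planted-recovery tests therefore demonstrates the
coordinate bookkeeping and grouping logic, not robustness to real
alignment error; on real data, co-location is only as good as the
alignment itself.

## Problem sizes and numerical choices

Property suites run at: 200 random alignments for FASTA round-trips,
1 000 random gapped strings for the coordinate bijection, 500 random
alignments (narrow alphabet, forcing ties) against an independently coded
consensus oracle, and 100 random fixture specifications with gap rates
0–0.3 for planted-pair recovery. The end-to-end check renders a
50-sequence × 1 000-column alignment carrying 200 annotations to HTML and
PNG. All are exact comparisons — the pipeline is discrete; there are no
tolerances to tune.

## Known limitations

- Only substitution tokens are parsed; other HGVS forms are display text.
- No codon arithmetic: genomic↔protein coordinate lifting is out of scope,
  as is projecting annotations between two different alignments.
- The HTML viewer is static; there is no client-side sorting, hiding or
  URL sharing.
- The PNG rasterizer understands the package's own SVG vocabulary only;
  arbitrary SVG is out of scope.
- Label-prefix selection can become ambiguous as alignments grow; indices
  always work.
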