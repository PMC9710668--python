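"""Generate a synthetic alignment with planted ground truth and verify it.

The generator plants variant pairs that are guaranteed to co-locate in one
column; running the full pipeline must recover exactly those groups.
"""

from alnmark import (
    ToySpec,
    index_by_column,
    load_annotations,
    make_fixture,
    ortho_groups,
)

spec = ToySpec(n_sequences=6, ungapped_length=80, gap_rate=0.2,
               n_variant_pairs=5, n_lone_variants=3, seed=42)
fx = make_fixture(spec)
aln = fx.alignment
aset = load_annotations(fx.json_text, aln)
groups = ortho_groups(index_by_column(aset, aln))

print(f"alignment: {len(aln)} x {aln.n_columns} columns, gap rate {spec.gap_rate}")
print(f"planted pairs at columns: {[g.column for g in fx.groups]}")
print(f"recovered groups at:      {[g.column for g in groups]}")
assert [g.column for g in groups] == [g.column for g in fx.groups]
print("recovery exact: every planted pair found, no false groups")
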