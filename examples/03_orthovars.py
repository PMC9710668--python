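"""Detect cross-species co-located variants (orthologous variants).

Annotation positions are native (ungapped) coordinates; two variants with
different native positions form an orthologous pair when gap patterns place
them in the same alignment column — e.g. a human variant at residue 4957
and its mouse counterpart at residue 4956.
"""

import json

from alnmark import index_by_column, load_annotations, ortho_groups, read_fasta

# Miniature of the RYR2 situation: the mouse row lacks one residue upstream,
# so native positions 5 (human) and 4 (mouse) share a column.
aln = read_fasta(">human RYR2-like\nMAKCV\n>mouse Ryr2-like\nM-KCV\n")
annotations = json.dumps(
    {
        "variants": [
            {"sequence": 0, "position": 4, "token": "p.C4Y", "source": "ClinVar"},
            {"sequence": 1, "position": 3, "token": "p.C3Y", "source": "MGI"},
        ]
    }
)

aset = load_annotations(annotations, aln)
groups = ortho_groups(index_by_column(aset, aln))
for group in groups:
    members = ", ".join(
        f"{aln.records[v.seq_index].label}:{v.token}" for v in group.members
    )
    print(f"column {group.column}: {members}")

# One group at column 4: the two substitutions hit homologous residues even
# though their native positions differ by one.
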