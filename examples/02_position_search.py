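"""Map between native residue positions and alignment columns.

Gaps shift columns relative to the ungapped sequence, so 'residue 4 of the
first protein' is generally not column 4.
"""

from alnmark import GAP, build_position_map, column_to_ungapped, find_position, read_fasta

aln = read_fasta(">human\nMA-KCV\n>mouse\nMAAKCV\n")

idx, column = find_position(aln, "human", 4)
print(f"residue 4 of {aln.records[idx].label} sits in alignment column {column}")

pmap = build_position_map(aln, 0)
for col in range(1, aln.n_columns + 1):
    pos = column_to_ungapped(pmap, col)
    print(f"  column {col}: {'gap' if pos is GAP else f'residue {pos}'}")

# The human row has a gap at column 3, so its residues 3..5 occupy
# columns 4..6 — the inverse map returns a GAP sentinel at gap columns.
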