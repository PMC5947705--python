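"""Trim an alignment to its conserved blocks before tree inference.

Columns are classified by how many rows share the most frequent residue;
long nonconserved runs, gap columns and short blocks are removed.
"""

from asrpipe.seqio import Alignment, Sequence
from asrpipe.trim import apply_blocks, select_conserved_blocks

# 8 sequences, 30 columns: conserved flanks around a 9-column noisy stretch
conserved_left = "KYWPLRHEND"
conserved_right = "VMIGSTAQFCE"
noisy = "AAAACCCC"  # each noisy column splits the taxa 4:4
rows = [conserved_left + noisy[r] * 9 + conserved_right for r in range(8)]
aln = Alignment([Sequence(f"seq{r}", row, "aa") for r, row in enumerate(rows)])

selection = select_conserved_blocks(aln)
print(selection.report())
trimmed = apply_blocks(aln, selection)
print(f"kept {selection.kept_columns} of {aln.n_columns} columns")
print("trimmed first row:", trimmed.sequences[0].residues)
# The 9-column noisy stretch exceeds the allowed run of 8 nonconserved
# columns, so only the two conserved flanking blocks survive.
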