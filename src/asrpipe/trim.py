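"""Conserved-block selection for alignment refinement.

Implements the classical block-trimming procedure used to strip poorly
aligned regions before tree inference: columns are classified by how many
rows share the most frequent residue, long runs of nonconserved columns and
gap-containing columns are rejected, candidate blocks are trimmed back to
high-conservation ("flank") boundaries, and short blocks are dropped.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
import math

from .seqio import GAP, Alignment


@dataclass(frozen=True)
class TrimParameters:
    """Block-selection thresholds.

    Defaults follow the classical conventions: a column is conserved when
    more than half the rows (floor(n/2)+1) share a residue, flank-quality
    when at least 85% do, at most 8 contiguous nonconserved columns survive
    inside a block, blocks must span at least 10 columns, and no kept column
    may contain a gap (``max_gap_fraction`` 0; raise it to relax).
    """

    min_conserved_count: int | None = None   # default floor(n/2)+1
    min_flank_count: int | None = None       # default ceil(0.85 n)
    max_contiguous_nonconserved: int = 8
    min_block_length: int = 10
    max_gap_fraction: float = 0.0

    def resolved(self, n_taxa: int) -> "TrimParameters":
        mc = self.min_conserved_count
        mf = self.min_flank_count
        if mc is None:
            mc = n_taxa // 2 + 1
        if mf is None:
            mf = math.ceil(0.85 * n_taxa)
        return TrimParameters(
            mc, mf, self.max_contiguous_nonconserved,
            self.min_block_length, self.max_gap_fraction,
        )


@dataclass
class BlockSelection:
    blocks: list[tuple[int, int]]            # inclusive, 1-based
    parameters: TrimParameters
    column_status: list[str] = field(default_factory=list)

    @property
    def kept_columns(self) -> int:
        return sum(e - s + 1 for s, e in self.blocks)

    def columns(self) -> list[int]:
        out: list[int] = []
        for s, e in self.blocks:
            out.extend(range(s, e + 1))
        return out

    def report(self) -> str:
        lines = ["block_index\tstart\tend\tlength"]
        for i, (s, e) in enumerate(self.blocks, start=1):
            lines.append(f"{i}\t{s}\t{e}\t{e - s + 1}")
        return "\n".join(lines) + "\n"


def _classify_column(column: list[str], params: TrimParameters) -> str:
    """conserved / flank / noncons / gap for one column.

    Ambiguity characters (X/N) never count toward the majority; ties for the
    most frequent residue are broken alphabetically (the count is the same
    either way, so this affects bookkeeping only).
    """
    n_gap = sum(1 for ch in column if ch == GAP)
    if n_gap > params.max_gap_fraction * len(column):
        return "gap"
    counts = Counter(ch for ch in column if ch not in (GAP, "X", "N"))
    top = max(counts.values(), default=0)
    if top >= params.min_flank_count:
        return "flank"
    if top >= params.min_conserved_count:
        return "conserved"
    return "noncons"


def select_conserved_blocks(
    alignment: Alignment, parameters: TrimParameters | None = None
) -> BlockSelection:
    """Select conserved blocks of an amino-acid (or nucleotide) alignment."""
    if alignment.n_taxa < 2:
        raise ValueError("block selection needs at least 2 sequences")
    params = (parameters or TrimParameters()).resolved(alignment.n_taxa)
    n = alignment.n_columns
    status = [_classify_column(alignment.column(c), params) for c in range(1, n + 1)]

    rejected = [st == "gap" for st in status]
    # runs of contiguous nonconserved columns longer than the cutoff
    run_start = None
    for c in range(n + 1):
        nonc = c < n and status[c] == "noncons"
        if nonc and run_start is None:
            run_start = c
        elif not nonc and run_start is not None:
            if c - run_start > params.max_contiguous_nonconserved:
                for j in range(run_start, c):
                    rejected[j] = True
            run_start = None

    # candidate blocks = maximal runs of unrejected columns, trimmed so both
    # boundaries are flank-quality, then length-filtered
    blocks: list[tuple[int, int]] = []
    c = 0
    while c < n:
        if rejected[c]:
            c += 1
            continue
        start = c
        while c < n and not rejected[c]:
            c += 1
        end = c - 1
        while start <= end and status[start] != "flank":
            start += 1
        while end >= start and status[end] != "flank":
            end -= 1
        if start <= end and end - start + 1 >= params.min_block_length:
            blocks.append((start + 1, end + 1))  # to 1-based
    return BlockSelection(blocks, params, column_status=status)


def apply_blocks(alignment: Alignment, selection: BlockSelection) -> Alignment:
    """Concatenate the selected blocks into a trimmed alignment (row order
    preserved; an empty selection yields a zero-column alignment)."""
    for s, e in selection.blocks:
        if not (1 <= s <= e <= alignment.n_columns):
            raise ValueError(f"block ({s},{e}) out of range 1..{alignment.n_columns}")
    return alignment.take_columns(selection.columns())
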