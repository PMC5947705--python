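"""Three-track consensus of ancestral sequences, ambiguity resolution and
back-translation.

The amino-acid, nucleotide and codon inference tracks are first translated
to amino acids and compared column by column.  Unanimous columns are fixed;
disagreements are flagged and then resolved by a fixed, reproducible rule
order: an explicit manual override (where chemistry or structure knowledge
enters as a recorded human decision), else the codon-track residue when its
MAP posterior clears a confidence threshold (codon inference being the most
robust track), else the most frequent residue among the extant sequences in
that column, with ties going to the codon-track residue.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from . import models as M
from .seqio import GAP, Alignment, Sequence

logger = logging.getLogger(__name__)

VERDICTS = (
    "unanimous",
    "resolved_by_codon",
    "resolved_by_extant_majority",
    "manual_override",
    "gap",
)


@dataclass
class ColumnCall:
    column: int                    # 1-based
    residue: str                   # amino acid or '-'
    verdict: str
    candidates: tuple = ()
    ambiguous: bool = False


@dataclass
class ConsensusResult:
    calls: list[ColumnCall]
    metrics: dict = field(default_factory=dict)

    @property
    def n_columns(self) -> int:
        return len(self.calls)

    @property
    def non_gap_columns(self) -> int:
        return sum(1 for c in self.calls if c.verdict != "gap")

    @property
    def ambiguous_fraction(self) -> float:
        non_gap = self.non_gap_columns
        if non_gap == 0:
            return 0.0
        return sum(1 for c in self.calls if c.ambiguous) / non_gap

    @property
    def is_resolved(self) -> bool:
        return all(c.verdict != "flagged" for c in self.calls)

    def sequence(self, identifier: str = "consensus") -> Sequence:
        return Sequence(identifier, "".join(c.residue for c in self.calls), "aa")


def three_way_consensus(
    aa_track: str,
    nt_track_translated: str,
    codon_track_translated: str,
    gap_mask: np.ndarray | None = None,
) -> ConsensusResult:
    """Column-wise comparison of the three translated tracks.

    Unanimous columns are fixed immediately; any disagreement flags the
    column (verdict 'flagged') for :func:`resolve_ambiguities`.  Gap-masked
    columns become '-' regardless of the tracks.
    """
    n = len(aa_track)
    if len(nt_track_translated) != n or len(codon_track_translated) != n:
        raise ValueError(
            "track length mismatch: "
            f"aa {n}, nt {len(nt_track_translated)}, codon {len(codon_track_translated)}"
        )
    if gap_mask is None:
        gap_mask = np.zeros(n, dtype=bool)
    calls = []
    for c in range(n):
        if gap_mask[c]:
            calls.append(ColumnCall(c + 1, GAP, "gap"))
            continue
        trio = (aa_track[c], nt_track_translated[c], codon_track_translated[c])
        if trio[0] == trio[1] == trio[2]:
            calls.append(ColumnCall(c + 1, trio[0], "unanimous", (trio[0],)))
        else:
            cands = tuple(sorted(set(trio)))
            calls.append(ColumnCall(c + 1, "X", "flagged", cands, ambiguous=True))
    return ConsensusResult(calls)


def resolve_ambiguities(
    result: ConsensusResult,
    codon_track_translated: str,
    codon_confidences: np.ndarray,
    extant_alignment: Alignment | None = None,
    codon_confidence_threshold: float = 0.5,
    manual_overrides: dict[int, str] | None = None,
) -> ConsensusResult:
    """Resolve flagged columns in a fixed order; idempotent.

    Per flagged column: (a) a manual override wins; (b) else the codon-track
    residue if its MAP posterior >= the threshold; (c) else the most frequent
    extant residue in that column, ties in favour of the codon-track residue.
    Ambiguity flags are retained for reporting after resolution.
    """
    if not 0 <= codon_confidence_threshold <= 1:
        raise ValueError("codon confidence threshold must lie in [0,1]")
    manual_overrides = manual_overrides or {}
    for call in result.calls:
        if call.verdict != "flagged":
            continue
        col = call.column
        codon_res = codon_track_translated[col - 1]
        if col in manual_overrides:
            residue = manual_overrides[col]
            if residue not in call.candidates:
                logger.warning(
                    "column %d: override residue %r not among candidates %s; applied anyway",
                    col, residue, call.candidates,
                )
            call.residue = residue
            call.verdict = "manual_override"
        elif codon_confidences[col - 1] >= codon_confidence_threshold:
            call.residue = codon_res
            call.verdict = "resolved_by_codon"
        else:
            counts: Counter = Counter()
            if extant_alignment is not None:
                counts = Counter(
                    ch
                    for ch in extant_alignment.column(col)
                    if ch not in (GAP, "X")
                )
            if counts:
                top = max(counts.values())
                leaders = sorted(r for r, k in counts.items() if k == top)
                call.residue = codon_res if codon_res in leaders else leaders[0]
            else:
                call.residue = codon_res
            call.verdict = "resolved_by_extant_majority"
    result.metrics["ambiguous_fraction"] = result.ambiguous_fraction
    return result


def ambiguity_report(result: ConsensusResult):
    """Flagged-column table plus the headline ambiguous fraction."""
    import pandas as pd

    rows = [
        {
            "column": c.column,
            "candidates": "/".join(c.candidates),
            "residue": c.residue,
            "verdict": c.verdict,
        }
        for c in result.calls
        if c.ambiguous
    ]
    table = pd.DataFrame(rows, columns=["column", "candidates", "residue", "verdict"])
    return table, result.ambiguous_fraction


# ---------------------------------------------------------------------------
# Back-translation

_CANONICAL_CODON: dict[str, str] = {}
for _codon in M.CODON_STATES:  # alphabetical, so first hit is canonical
    _aa = M.translate_codon(_codon)
    _CANONICAL_CODON.setdefault(_aa, _codon)


def backtranslate(
    ancestor: Sequence,
    codon_track: Sequence | None = None,
    codon_usage_table: dict[str, float] | None = None,
) -> Sequence:
    """Back-translate an amino-acid ancestor to DNA.

    Per residue: the codon-track MAP codon is kept when it translates to that
    residue; otherwise the highest-frequency codon for the residue from the
    usage table (default: first codon in a fixed canonical order).  The output
    translates back to the input exactly.
    """
    if ancestor.alphabet != "aa":
        raise ValueError("back-translation expects an amino-acid sequence")
    if GAP in ancestor.residues:
        raise ValueError("remove gap columns before back-translation")
    codons = []
    track = codon_track.residues if codon_track is not None else ""
    for i, res in enumerate(ancestor.residues):
        if res not in _CANONICAL_CODON or res == "X":
            raise ValueError(f"residue {res!r} at position {i + 1} has no codon")
        choice = None
        if codon_track is not None and 3 * i + 3 <= len(track):
            cand = track[3 * i : 3 * i + 3]
            if M.translate_codon(cand) == res:
                choice = cand
        if choice is None and codon_usage_table:
            options = [c for c in M.CODON_STATES if M.translate_codon(c) == res]
            choice = max(options, key=lambda c: (codon_usage_table.get(c, 0.0), [-ord(x) for x in c]))
        if choice is None:
            choice = _CANONICAL_CODON[res]
        codons.append(choice)
    return Sequence(ancestor.identifier + "_dna", "".join(codons), "nt")
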