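"""Empirical-Bayes marginal ancestral reconstruction.

For a fixed tree with optimized branch lengths, the marginal posterior of
state x at an internal node is proportional to the stationary frequency of x
times the conditional likelihoods of the subtrees hanging off that node,
transported through the transition matrices of the incident branches.  Rate
categories are mixed by their per-site posterior weights.  Three tracks
(amino acid, nucleotide, codon) share this machinery with different models;
ancestral gap states come from Fitch parsimony on presence/absence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import models as M
from .mltree import LikelihoodEngine
from .seqio import GAP, Alignment, Node, PhyloTree, Sequence

logger = logging.getLogger(__name__)


@dataclass
class PosteriorTable:
    """Per-column state posteriors at one internal node."""

    node_label: str
    states: tuple
    probabilities: np.ndarray  # (n_columns, n_states), rows sum to 1

    @property
    def n_columns(self) -> int:
        return self.probabilities.shape[0]

    @property
    def map_indices(self) -> np.ndarray:
        return self.probabilities.argmax(axis=1)

    @property
    def map_states(self) -> list[str]:
        return [self.states[i] for i in self.map_indices]

    @property
    def map_probabilities(self) -> np.ndarray:
        return self.probabilities.max(axis=1)

    def dump(self) -> str:
        """Tab-separated posterior dump (node, column, state, probability, is_map)."""
        lines = ["node\tcolumn\tstate\tprobability\tis_map"]
        maps = self.map_indices
        for c in range(self.n_columns):
            for si, state in enumerate(self.states):
                p = self.probabilities[c, si]
                if p < 1e-6 and si != maps[c]:
                    continue
                lines.append(
                    f"{self.node_label}\t{c + 1}\t{state}\t{p:.6f}\t{int(si == maps[c])}"
                )
        return "\n".join(lines) + "\n"


@dataclass
class AncestralSequence:
    node_label: str
    sequence: Sequence
    confidence: np.ndarray  # per column, in (0,1]


def marginal_posteriors(
    tree: PhyloTree,
    alignment: Alignment,
    model: M.RateMatrix,
    site_rates: M.SiteRateModel | None = None,
    node: Node | None = None,
) -> PosteriorTable:
    """Marginal posterior state probabilities at an internal node.

    ``node`` must be an internal node of ``tree`` (default: the root).
    Columns that carry no data get the stationary distribution.
    """
    if node is None:
        node = tree.root
    if node.is_leaf:
        raise ValueError("ancestral states are defined for internal nodes only")
    engine = LikelihoodEngine(tree, alignment, model, site_rates)
    joint = engine.node_state_loglik(node)  # (k, S, patterns)
    logw = np.log(engine.site_rates.weights)[:, None, None]
    a = joint + logw
    amax = a.max(axis=(0, 1), keepdims=True)
    num = np.exp(a - amax).sum(axis=0)  # (S, patterns)
    post = num / num.sum(axis=0, keepdims=True)
    probs = post.T[engine.site_to_pattern]  # expand patterns to columns
    return PosteriorTable(node.label or "node", model.states, probs)


def map_sequence(
    posteriors: PosteriorTable, gap_mask: np.ndarray | None = None
) -> AncestralSequence:
    """MAP state per column, with gap-masked columns forced to '-'.

    Exact posterior ties are broken by state order (alphabetical) with a
    logged warning.
    """
    n = posteriors.n_columns
    if gap_mask is None:
        gap_mask = np.zeros(n, dtype=bool)
    if len(gap_mask) != n:
        raise ValueError("gap mask length does not match posterior columns")
    probs = posteriors.probabilities
    maps = posteriors.map_indices
    best = posteriors.map_probabilities
    ties = (np.abs(probs - best[:, None]) < 1e-12).sum(axis=1) > 1
    for c in np.nonzero(ties)[0]:
        logger.warning(
            "node %s column %d: posterior tie broken by state order",
            posteriors.node_label, c + 1,
        )
    is_codon = len(posteriors.states) == 61
    gap_char = "---" if is_codon else GAP
    chars = []
    for c in range(n):
        chars.append(gap_char if gap_mask[c] else posteriors.states[maps[c]])
    alphabet = "codon" if is_codon else ("nt" if len(posteriors.states) == 4 else "aa")
    seq = Sequence(posteriors.node_label, "".join(chars), alphabet)
    return AncestralSequence(posteriors.node_label, seq, best.copy())


# ---------------------------------------------------------------------------
# Ancestral gaps (Fitch parsimony on presence/absence)

_PRESENT, _GAP = 2, 1  # bitmask encoding


def infer_ancestral_gaps(
    tree: PhyloTree, alignment: Alignment, node: Node | None = None
) -> np.ndarray:
    """Per-column gap mask (True = ancestral gap) at an internal node.

    Leaf states are coded present/gap; a Fitch up-pass (intersection if
    nonempty, else union) and down-pass assign each internal node a state,
    with ties resolved to 'present' so residues survive for downstream
    resolution.
    """
    if not tree.rooted:
        raise ValueError("ancestral gap inference needs a rooted tree")
    if node is None:
        node = tree.root
    if node.is_leaf:
        raise ValueError("gap states are inferred for internal nodes only")
    n_cols = alignment.n_columns
    row_of = {ident: r for r, ident in enumerate(alignment.identifiers)}
    present = np.zeros((alignment.n_taxa, n_cols), dtype=bool)
    for r, seq in enumerate(alignment.sequences):
        for c in range(1, n_cols + 1):
            present[r, c - 1] = GAP not in seq.column(c)

    upsets: dict[int, np.ndarray] = {}
    for v in tree.postorder():
        if v.is_leaf:
            upsets[id(v)] = np.where(present[row_of[v.label]], _PRESENT, _GAP)
        else:
            inter = np.full(n_cols, _PRESENT | _GAP, dtype=np.int64)
            union = np.zeros(n_cols, dtype=np.int64)
            for c in v.children:
                inter &= upsets[id(c)]
                union |= upsets[id(c)]
            upsets[id(v)] = np.where(inter > 0, inter, union)

    final: dict[int, np.ndarray] = {}
    for v in tree.preorder():
        s = upsets[id(v)]
        if v.parent is None:
            # tie -> present
            final[id(v)] = np.where(s & _PRESENT, _PRESENT, _GAP)
        else:
            pf = final[id(v.parent)]
            keep_parent = (s & pf) > 0
            own = np.where(s & _PRESENT, _PRESENT, _GAP)  # tie -> present
            final[id(v)] = np.where(keep_parent, pf, own)
    return final[id(node)] == _GAP


# ---------------------------------------------------------------------------
# Confidence metrics


@dataclass
class ConfidenceMetrics:
    per_track: dict[str, float]     # track name -> mean MAP posterior
    overall_average_posterior: float
    n_columns_used: int

    def as_text(self) -> str:
        lines = []
        for name in sorted(self.per_track):
            lines.append(f"confidence_{name}\t{self.per_track[name]:.5f}")
        lines.append(f"overall_average_posterior\t{self.overall_average_posterior:.4f}")
        lines.append(f"n_columns_used\t{self.n_columns_used}")
        return "\n".join(lines) + "\n"


def confidence_metrics(
    posteriors_per_track: dict[str, PosteriorTable], gap_mask: np.ndarray
) -> ConfidenceMetrics:
    """Per-track confidence = mean MAP posterior over non-gap columns;
    overall = mean over tracks and non-gap columns."""
    keep = ~np.asarray(gap_mask, dtype=bool)
    if not keep.any():
        raise ValueError("no non-gap columns to compute confidence over")
    per_track = {}
    all_vals = []
    for name, table in posteriors_per_track.items():
        if table.n_columns == 3 * len(keep):  # nucleotide view of codon columns
            track_keep = np.repeat(keep, 3)
        elif table.n_columns == len(keep):
            track_keep = keep
        else:
            raise ValueError(f"track {name!r} column count mismatch")
        vals = table.map_probabilities[track_keep]
        per_track[name] = float(vals.mean())
        all_vals.append(vals)
    overall = float(np.concatenate(all_vals).mean())
    return ConfidenceMetrics(per_track, overall, int(keep.sum()))
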