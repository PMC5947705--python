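"""Synthetic data with known ancestors: birth-death time-trees and codon
sequence evolution with indels.

Sequences evolve at codon granularity under a reversible codon model with
discrete rate categories, simulated per site by the Gillespie algorithm so
that a full event log exists.  Indels insert or delete whole codons and are
threaded into one global alignment, which keeps the amino-acid, nucleotide
and codon views of the data exactly column-compatible.  True sequences are
recorded at every node, making every downstream stage testable against a
known answer.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
from dendropy.simulate import treesim

from . import models as M
from .dating import Chronogram
from .seqio import Alignment, Node, PhyloTree, Sequence

GAP_CODON = "---"


@dataclass
class IndelEvent:
    branch: str          # child-node label
    kind: str            # 'insertion' | 'deletion' | 'substitution'
    column: int          # global column id
    detail: str


@dataclass
class SimTruth:
    """Everything the simulator knows: tree, per-branch substitution lengths,
    true codon sequence at every node on a shared global column grid, and the
    event log."""

    tree: PhyloTree                       # ages set; labels on all nodes
    column_order: list[int]
    node_codons: dict[str, dict[int, str]]
    site_categories: dict[int, int]
    subs_lengths: dict[str, float]        # child label -> subs/codon-site
    events: list[IndelEvent] = field(default_factory=list)

    def codon_string(self, label: str) -> str:
        seq = self.node_codons[label]
        return "".join(seq.get(col, GAP_CODON) for col in self.column_order)

    def event_log(self) -> str:
        lines = ["branch\tkind\tcolumn\tdetail"]
        for e in self.events:
            lines.append(f"{e.branch}\t{e.kind}\t{e.column}\t{e.detail}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Trees


def simulate_tree(
    n_taxa: int,
    birth_rate: float = 1.0,
    death_rate: float = 0.0,
    root_age: float = 100.0,
    seed: int = 0,
) -> Chronogram:
    """Birth-death tree conditioned on ``n_taxa`` extant tips, rescaled so the
    root sits at ``root_age`` (Myr).  Reproducible by seed."""
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    if death_rate > birth_rate:
        raise ValueError("death rate must not exceed birth rate")
    if n_taxa == 2:
        root = Node("root")
        for i in (1, 2):
            leaf = root.add_child(Node(f"t{i}", root_age))
        tree = PhyloTree(root)
    else:
        rng = random.Random(seed)
        dtree = treesim.birth_death_tree(
            birth_rate=birth_rate,
            death_rate=death_rate,
            num_extant_tips=n_taxa,
            rng=rng,
        )
        for i, leaf in enumerate(dtree.leaf_node_iter(), start=1):
            leaf.taxon.label = f"t{i}"
        from .seqio import parse_newick

        tree = parse_newick(dtree.as_string(schema="newick").replace("'", ""))
        # rescale durations so the deepest tip path equals root_age
        depth = {id(tree.root): 0.0}
        deepest = 0.0
        for n in tree.preorder():
            if n.parent is not None:
                depth[id(n)] = depth[id(n.parent)] + n.length
                deepest = max(deepest, depth[id(n)])
        scale = root_age / deepest
        for n in tree.postorder():
            n.length *= scale
    tree.set_ages_from_branch_durations()
    for leaf in tree.leaves():  # extant tips: force exact zeros
        leaf.age = 0.0
    label_internal_nodes(tree)
    tree.rooted = True
    return Chronogram(tree)


def label_internal_nodes(tree: PhyloTree, prefix: str = "node") -> None:
    k = 0
    for n in tree.preorder():
        if not n.is_leaf and not n.label:
            k += 1
            n.label = f"{prefix}{k}"


def add_outgroup(
    chron: Chronogram, label: str = "outgrp", stem_factor: float = 1.5
) -> Chronogram:
    """Attach a single outgroup leaf diverging above the ingroup root, giving
    the pipeline a real rooting and calibration target."""
    tree = chron.tree.copy()
    old_root = tree.root
    new_age = old_root.age * stem_factor
    new_root = Node("root0")
    new_root.age = new_age
    new_root.add_child(old_root)
    old_root.length = new_age - old_root.age
    out = new_root.add_child(Node(label, new_age))
    out.age = 0.0
    return Chronogram(PhyloTree(new_root, rooted=True))


# ---------------------------------------------------------------------------
# Sequence evolution


def _draw_codon(rng: np.random.Generator, pi_cum: np.ndarray) -> int:
    return int(np.searchsorted(pi_cum, rng.random()))


def simulate_evolution(
    chron: Chronogram,
    codon_model: M.RateMatrix,
    site_rates: M.SiteRateModel | None = None,
    n_codons: int = 300,
    indel_rate: float = 0.0,
    root_sequence: str | None = None,
    seed: int = 0,
    clock_rate: float | None = None,
    rate_sigma: float = 0.0,
) -> SimTruth:
    """Evolve codon sequences down a time-tree.

    Branch substitution lengths are duration * clock_rate, optionally
    jittered by a lognormal factor with log-sd ``rate_sigma`` (a relaxed
    clock); with ``clock_rate`` None the tree's existing branch lengths are
    used verbatim.  Substitutions run per site by the Gillespie algorithm
    under the site's rate category; indels act on whole codons (rate per
    codon site per unit branch length, geometric lengths with mean 2) and are
    applied at the start of each branch.
    """
    if n_codons < 1:
        raise ValueError("need at least one codon")
    if indel_rate < 0:
        raise ValueError("indel rate must be nonnegative")
    site_rates = site_rates or M.uniform_rates()
    tree = chron.tree
    label_internal_nodes(tree)
    Q = codon_model.Q
    n_states = codon_model.n_states
    exit_rates = -np.diag(Q)
    jump_cum = np.cumsum(
        np.where(np.eye(n_states, dtype=bool), 0.0, Q) / exit_rates[:, None], axis=1
    )
    pi_cum = np.cumsum(codon_model.frequencies)
    rate_cum = np.cumsum(site_rates.weights)

    root_rng = np.random.default_rng([seed, 999_983])
    if root_sequence is None:
        root_states = [ _draw_codon(root_rng, pi_cum) for _ in range(n_codons) ]
    else:
        if len(root_sequence) != 3 * n_codons:
            raise ValueError("root sequence length does not match n_codons")
        root_states = []
        for i in range(0, len(root_sequence), 3):
            codon = root_sequence[i : i + 3]
            if codon in M.STOP_CODONS:
                raise ValueError(f"stop codon {codon} in requested root sequence")
            root_states.append(M.CODON_STATES.index(codon))

    column_order = list(range(n_codons))
    next_col = n_codons
    site_cat = {
        c: int(np.searchsorted(rate_cum, root_rng.random())) for c in column_order
    }
    node_states: dict[str, dict[int, int]] = {
        tree.root.label: dict(zip(column_order, root_states))
    }
    subs_lengths: dict[str, float] = {}
    events: list[IndelEvent] = []

    order = [n for n in tree.preorder() if n.parent is not None]
    for branch_idx, child in enumerate(order):
        rng = np.random.default_rng([seed, branch_idx])
        if clock_rate is None:
            b = child.length
        else:
            dur = child.parent.age - child.age
            jitter = float(np.exp(rng.normal(0.0, rate_sigma))) if rate_sigma > 0 else 1.0
            b = dur * clock_rate * jitter
            child.length = b
        subs_lengths[child.label] = b
        seq = dict(node_states[child.parent.label])

        if indel_rate > 0 and seq:
            present = [c for c in column_order if c in seq]
            n_events = rng.poisson(indel_rate * b * len(present))
            for _ in range(n_events):
                if not present:
                    break
                pos = int(rng.integers(len(present)))
                length = int(rng.geometric(0.5))
                if rng.random() < 0.5:  # deletion
                    for c in present[pos : pos + length]:
                        seq.pop(c, None)
                        events.append(IndelEvent(child.label, "deletion", c, f"len{length}"))
                    present = [c for c in present if c in seq]
                else:  # insertion after the chosen column
                    anchor = present[pos]
                    at = column_order.index(anchor) + 1
                    new_cols = list(range(next_col, next_col + length))
                    next_col += length
                    column_order[at:at] = new_cols
                    for c in new_cols:
                        seq[c] = _draw_codon(rng, pi_cum)
                        site_cat[c] = int(np.searchsorted(rate_cum, rng.random()))
                        events.append(IndelEvent(child.label, "insertion", c, f"len{length}"))
                    present = [c for c in column_order if c in seq]

        # Gillespie substitutions, per present site
        for c in list(seq):
            r = site_rates.rates[site_cat[c]]
            if r <= 0 or b <= 0:
                continue
            state = seq[c]
            t = 0.0
            while True:
                exit_rate = exit_rates[state] * r
                if exit_rate <= 0:
                    break
                t += rng.exponential(1.0 / exit_rate)
                if t > b:
                    break
                new = int(np.searchsorted(jump_cum[state], rng.random()))
                events.append(
                    IndelEvent(
                        child.label, "substitution", c,
                        f"{M.CODON_STATES[state]}>{M.CODON_STATES[new]}@{t:.4f}",
                    )
                )
                state = new
            seq[c] = state
        node_states[child.label] = seq

    node_codons = {
        label: {c: M.CODON_STATES[s] for c, s in states.items()}
        for label, states in node_states.items()
    }
    return SimTruth(tree, column_order, node_codons, site_cat, subs_lengths, events)


# ---------------------------------------------------------------------------
# Generic single-alphabet simulation (no indels)


def simulate_sites(
    tree: PhyloTree,
    model: M.RateMatrix,
    site_rates: M.SiteRateModel | None = None,
    n_sites: int = 300,
    seed: int = 0,
):
    """Evolve i.i.d. sites on a tree with branch lengths in subs/site.

    Draws the root from the stationary distribution and children from the
    exact transition matrices (no event log, no indels); useful for testing
    inference under amino-acid or nucleotide models directly.  Returns
    (leaf Alignment, true states per node as a dict label -> index array).
    """
    site_rates = site_rates or M.uniform_rates()
    label_internal_nodes(tree)
    rng = np.random.default_rng([seed, 777_001])
    pi_cum = np.cumsum(model.frequencies)
    cats = np.searchsorted(np.cumsum(site_rates.weights), rng.random(n_sites))
    states: dict[str, np.ndarray] = {
        tree.root.label: np.searchsorted(pi_cum, rng.random(n_sites))
    }
    for branch_idx, child in enumerate(
        n for n in tree.preorder() if n.parent is not None
    ):
        brng = np.random.default_rng([seed, 777_002, branch_idx])
        parent_states = states[child.parent.label]
        out = np.empty(n_sites, dtype=np.int64)
        for ci, rate in enumerate(site_rates.rates):
            mask = cats == ci
            if not mask.any():
                continue
            P = model.transition_matrix(child.length, rate)
            cum = np.cumsum(P, axis=1)
            u = brng.random(int(mask.sum()))
            rows = cum[parent_states[mask]]
            out[mask] = (u[:, None] > rows).sum(axis=1)
        states[child.label] = out
    alphabet = {20: "aa", 4: "nt"}.get(model.n_states, "codon")
    leaf_seqs = [
        Sequence(lf.label, "".join(model.states[i] for i in states[lf.label]), alphabet)
        for lf in tree.leaves()
    ]
    return Alignment(leaf_seqs), states


# ---------------------------------------------------------------------------
# Three-track export


def make_three_track_dataset(sim: SimTruth):
    """Leaf alignments in all three views plus true ancestors per node.

    Returns (aa_alignment, nt_alignment, codon_alignment, true_ancestors)
    where true_ancestors maps internal-node label -> dict with 'aa', 'nt',
    'codon' Sequences on the same global columns.
    """
    leaves = sim.tree.leaf_labels()
    codon_seqs, nt_seqs, aa_seqs = [], [], []
    for label in leaves:
        s = sim.codon_string(label)
        codon_seqs.append(Sequence(label, s, "codon"))
        nt_seqs.append(Sequence(label, s, "nt"))
        aa_seqs.append(Sequence(label, M.translate(s), "aa"))
    ancestors = {}
    for n in sim.tree.internal_nodes():
        s = sim.codon_string(n.label)
        ancestors[n.label] = {
            "codon": Sequence(n.label, s, "codon"),
            "nt": Sequence(n.label, s, "nt"),
            "aa": Sequence(n.label, M.translate(s), "aa"),
        }
    return Alignment(aa_seqs), Alignment(nt_seqs), Alignment(codon_seqs), ancestors
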