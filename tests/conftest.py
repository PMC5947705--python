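"""Shared fixtures and independent oracles.

The likelihood/posterior oracle here enumerates every assignment of states to
internal nodes (expressed as a naive tensor contraction with ``optimize=False``
so no factorization is applied) — deliberately independent of the pruning
recursion it checks.
"""

from __future__ import annotations

import string

import numpy as np
import pytest

from asrpipe import models as M
from asrpipe.mltree import encode_alignment
from asrpipe.seqio import Alignment, Node, PhyloTree, Sequence


# ---------------------------------------------------------------------------
# Random inputs


def random_binary_tree(n_leaves: int, rng: np.random.Generator) -> PhyloTree:
    nodes = [Node(f"L{i}", float(rng.uniform(0.05, 0.8))) for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = Node(None, float(rng.uniform(0.05, 0.8)))
        parent.add_child(a)
        parent.add_child(b)
        nodes.append(parent)
    root = nodes[0]
    root.length = 0.0
    k = 0
    tree = PhyloTree(root)
    for nd in tree.preorder():
        if not nd.is_leaf:
            k += 1
            nd.label = f"N{k}"
    return tree


def random_model(alphabet: str, rng: np.random.Generator) -> M.RateMatrix:
    if alphabet == "aa":
        freqs = rng.dirichlet(np.full(20, 5.0))
        return M.build_empirical_aa("WAG", freqs)
    if alphabet == "nt":
        ex = np.exp(rng.normal(0.0, 0.5, size=6))
        freqs = rng.dirichlet(np.full(4, 5.0))
        return M.build_gtr(ex, freqs)
    freqs = rng.dirichlet(np.full(61, 10.0))
    return M.build_codon(
        M.CodonModelParams(float(rng.uniform(1, 4)), float(rng.uniform(0.1, 2)), freqs)
    )


def random_site_rates(rng: np.random.Generator) -> M.SiteRateModel:
    if rng.random() < 0.5:
        return M.uniform_rates()
    return M.discrete_gamma(float(rng.uniform(0.3, 2.0)), 3)


def random_alignment(
    tree: PhyloTree, alphabet: str, n_cols: int, rng: np.random.Generator,
    missing_prob: float = 0.1,
) -> Alignment:
    states = {"aa": M.AA_STATES, "nt": M.NT_STATES, "codon": M.CODON_STATES}[alphabet]
    gap = "---" if alphabet == "codon" else "-"
    seqs = []
    for leaf in tree.leaves():
        chars = [
            gap if rng.random() < missing_prob else states[rng.integers(len(states))]
            for _ in range(n_cols)
        ]
        seqs.append(Sequence(leaf.label, "".join(chars), alphabet))
    return Alignment(seqs)


# ---------------------------------------------------------------------------
# Exhaustive-enumeration oracle


def _site_factors(tree: PhyloTree, model: M.RateMatrix, rate: float,
                  obs: dict[str, int]):
    """Build the einsum expression and operands for one site and category."""
    letters = iter(string.ascii_lowercase)
    index = {}
    for nd in tree.postorder():
        if not nd.is_leaf:
            index[id(nd)] = next(letters)
    subscripts = [index[id(tree.root)]]
    operands = [model.frequencies]
    for nd in tree.postorder():
        if nd.parent is None:
            continue
        P = model.transition_matrix(nd.length, rate)
        if nd.is_leaf:
            s = obs[nd.label]
            vec = P[:, s] if s >= 0 else np.ones(model.n_states)
            subscripts.append(index[id(nd.parent)])
            operands.append(vec)
        else:
            subscripts.append(index[id(nd.parent)] + index[id(nd)])
            operands.append(P)
    return subscripts, operands, index


def brute_force_site_likelihood(
    tree: PhyloTree, model: M.RateMatrix, site_rates: M.SiteRateModel,
    obs: dict[str, int],
) -> float:
    """Likelihood of one site by naive summation over all internal states."""
    total = 0.0
    for w, r in zip(site_rates.weights, site_rates.rates):
        subs, ops, _ = _site_factors(tree, model, r, obs)
        total += w * float(np.einsum(",".join(subs) + "->", *ops, optimize=False))
    return total


def brute_force_log_likelihood(
    tree: PhyloTree, alignment: Alignment, model: M.RateMatrix,
    site_rates: M.SiteRateModel,
) -> np.ndarray:
    mat = encode_alignment(alignment, model.states)
    out = []
    for c in range(mat.shape[1]):
        obs = {ident: int(mat[r, c]) for r, ident in enumerate(alignment.identifiers)}
        out.append(np.log(brute_force_site_likelihood(tree, model, site_rates, obs)))
    return np.array(out)


def brute_force_marginal(
    tree: PhyloTree, alignment: Alignment, model: M.RateMatrix,
    site_rates: M.SiteRateModel, node,
) -> np.ndarray:
    """(n_columns, n_states) marginal posterior at ``node`` by enumeration."""
    mat = encode_alignment(alignment, model.states)
    out = np.zeros((mat.shape[1], model.n_states))
    for c in range(mat.shape[1]):
        obs = {ident: int(mat[r, c]) for r, ident in enumerate(alignment.identifiers)}
        joint = np.zeros(model.n_states)
        for w, r in zip(site_rates.weights, site_rates.rates):
            subs, ops, index = _site_factors(tree, model, r, obs)
            target = index[id(node)]
            expr = ",".join(subs) + "->" + target
            joint += w * np.einsum(expr, *ops, optimize=False)
        out[c] = joint / joint.sum()
    return out


@pytest.fixture
def wag():
    return M.build_empirical_aa("WAG")


@pytest.fixture
def jc():
    return M.jukes_cantor()
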