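"""Maximum-likelihood tree inference.

The heart of the module is :class:`LikelihoodEngine`, a Felsenstein-pruning
implementation over discrete rate categories with per-node numerical scaling,
inside ("up") and outside ("out") partial vectors, and site-pattern
compression.  On top of it sit coordinate-wise branch-length optimization,
ML pairwise distances with a neighbor-joining starting tree, NNI
hill-climbing, nonparametric bootstrap and AIC model selection.

Unrooted trees are held with a basal trifurcation; likelihoods are invariant
to the placement of the virtual root because all models are time-reversible.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from . import models as M
from .seqio import Alignment, Node, PhyloTree, parse_newick

BL_MIN = 1e-8
BL_MAX = 20.0


class LikelihoodError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Alignment encoding


def encode_alignment(alignment: Alignment, states: tuple) -> np.ndarray:
    """Rows of state indices; -1 marks gap/ambiguity (treated as missing)."""
    index = {s: i for i, s in enumerate(states)}
    n_states = len(states)
    if n_states == 61:  # codon view: one column per triplet
        mat = np.empty((alignment.n_taxa, alignment.n_columns), dtype=np.int64)
        for r, seq in enumerate(alignment.sequences):
            for c in range(alignment.n_columns):
                mat[r, c] = index.get(seq.column(c + 1), -1)
    else:
        mat = np.empty((alignment.n_taxa, alignment.n_columns), dtype=np.int64)
        for r, seq in enumerate(alignment.sequences):
            for c, ch in enumerate(seq.residues):
                mat[r, c] = index.get(ch, -1)
    return mat


def compress_patterns(mat: np.ndarray):
    """Unique site patterns, their weights and the column->pattern map."""
    patterns, inverse, counts = np.unique(
        mat, axis=1, return_inverse=True, return_counts=True
    )
    return patterns, counts.astype(float), inverse


# ---------------------------------------------------------------------------
# Pruning engine


@dataclass
class LikelihoodResult:
    log_likelihood: float
    per_site_log_likelihoods: np.ndarray
    tree: PhyloTree
    model: M.RateMatrix
    site_rates: M.SiteRateModel


class LikelihoodEngine:
    """Pruning likelihood for one (tree, alignment, model, site-rates) tuple.

    The engine computes, per rate category, inside partials ``up[v]`` (the
    likelihood of the data below v conditional on the state at v) and outside
    partials ``out[v]`` (the stationary-weighted likelihood of everything
    else, transported to v), with per-pattern log scaling factors to avoid
    underflow.  ``out[v] * up[v]`` summed over states is the pattern
    likelihood from any node — the basis of both branch-length optimization
    and marginal ancestral posteriors.
    """

    def __init__(
        self,
        tree: PhyloTree,
        alignment: Alignment,
        model: M.RateMatrix,
        site_rates: M.SiteRateModel | None = None,
    ):
        self.tree = tree
        self.alignment = alignment
        self.model = model
        self.site_rates = site_rates or M.uniform_rates()
        leaf_set = set(tree.leaf_labels())
        aln_set = set(alignment.identifiers)
        if leaf_set != aln_set:
            raise LikelihoodError(
                f"tree/alignment mismatch: only in tree {sorted(leaf_set - aln_set)}, "
                f"only in alignment {sorted(aln_set - leaf_set)}"
            )
        mat = encode_alignment(alignment, model.states)
        self.patterns, self.pattern_weights, self.site_to_pattern = compress_patterns(mat)
        self.n_patterns = self.patterns.shape[1]
        self._row_of = {ident: r for r, ident in enumerate(alignment.identifiers)}
        self._dirty = True

    # -- passes ------------------------------------------------------------
    def _leaf_partial(self, node: Node) -> np.ndarray:
        """(k, n_states, n_patterns) one-hot partials; missing data -> ones."""
        n = self.model.n_states
        k = self.site_rates.n_categories
        states = self.patterns[self._row_of[node.label]]
        E = np.hstack([np.eye(n), np.ones((n, 1))])
        one = E[:, np.where(states < 0, n, states)]
        return np.broadcast_to(one, (k, n, self.n_patterns))

    def _compute(self) -> None:
        """Inside/outside pruning passes, all rate categories batched."""
        n = self.model.n_states
        k = self.site_rates.n_categories
        rates = self.site_rates.rates
        nodes = self.tree.postorder()
        up: dict[int, np.ndarray] = {}          # (k, n, patterns)
        upsc: dict[int, np.ndarray] = {}        # (k, patterns) log scale
        Pm: dict[int, np.ndarray] = {}          # (k, n, n)
        for v in nodes:
            if v.parent is not None:
                Pm[id(v)] = self.model.transition_stack(v.length, rates)
            if v.is_leaf:
                up[id(v)] = self._leaf_partial(v)
                upsc[id(v)] = np.zeros((k, self.n_patterns))
            else:
                acc = np.ones((k, n, self.n_patterns))
                sc = np.zeros((k, self.n_patterns))
                for c in v.children:
                    acc = acc * (Pm[id(c)] @ up[id(c)])
                    sc = sc + upsc[id(c)]
                m = acc.max(axis=1)
                m = np.where(m > 0, m, 1.0)
                up[id(v)] = acc / m[:, None, :]
                upsc[id(v)] = sc + np.log(m)
        pi = self.model.frequencies
        out: dict[int, np.ndarray] = {}
        outsc: dict[int, np.ndarray] = {}
        root = self.tree.root
        out[id(root)] = np.broadcast_to(pi[None, :, None], (k, n, self.n_patterns))
        outsc[id(root)] = np.zeros((k, self.n_patterns))
        for v in self.tree.preorder():
            if v.is_leaf:
                continue
            for c in v.children:
                acc = out[id(v)]
                sc = outsc[id(v)]
                for s in v.children:
                    if s is c:
                        continue
                    acc = acc * (Pm[id(s)] @ up[id(s)])
                    sc = sc + upsc[id(s)]
                m = acc.max(axis=1)
                m = np.where(m > 0, m, 1.0)
                out[id(c)] = np.swapaxes(Pm[id(c)], 1, 2) @ (acc / m[:, None, :])
                outsc[id(c)] = sc + np.log(m)
        self._up, self._up_scale = up, upsc
        self._out, self._out_scale = out, outsc
        self._P = Pm
        L = (pi[None, :, None] * up[id(root)]).sum(axis=1)
        L = np.clip(L, 1e-300, None)
        self._cat_pattern_ll = np.log(L) + upsc[id(root)]
        self._dirty = False

    def invalidate(self) -> None:
        self._dirty = True

    def _pattern_ll(self) -> np.ndarray:
        if self._dirty:
            self._compute()
        logw = np.log(self.site_rates.weights)[:, None]
        a = self._cat_pattern_ll + logw
        amax = a.max(axis=0)
        return amax + np.log(np.exp(a - amax).sum(axis=0))

    def log_likelihood(self) -> float:
        return float(self._pattern_ll() @ self.pattern_weights)

    def per_site_log_likelihoods(self) -> np.ndarray:
        return self._pattern_ll()[self.site_to_pattern]

    def result(self) -> LikelihoodResult:
        return LikelihoodResult(
            self.log_likelihood(),
            self.per_site_log_likelihoods(),
            self.tree,
            self.model,
            self.site_rates,
        )

    # -- category posteriors (empirical Bayes weights per site) -----------
    def category_posteriors(self) -> np.ndarray:
        """(k, n_patterns) posterior weight of each rate category per pattern."""
        if self._dirty:
            self._compute()
        logw = np.log(self.site_rates.weights)[:, None]
        a = self._cat_pattern_ll + logw
        a = a - a.max(axis=0)
        w = np.exp(a)
        return w / w.sum(axis=0)

    # -- node marginals (used by the ancestors module) ---------------------
    def node_state_loglik(self, node: Node) -> np.ndarray:
        """(k, n_states, n_patterns) log joint of (state at node, data) per
        category; exact for the root and any internal node."""
        if self._dirty:
            self._compute()
        prod = np.clip(self._out[id(node)] * self._up[id(node)], 1e-300, None)
        return (
            np.log(prod)
            + self._out_scale[id(node)][:, None, :]
            + self._up_scale[id(node)][:, None, :]
        )

    # -- single-branch profile --------------------------------------------
    def branch_profile(self, node: Node):
        """Return f(t) -> total log-likelihood as a function of the length of
        the branch above ``node``, with everything else held fixed."""
        if node.parent is None:
            raise LikelihoodError("root has no branch")
        if self._dirty:
            self._compute()
        # outside partial of the parent, excluding this child's subtree
        u = node.parent
        acc = self._out[id(u)]
        sc = self._out_scale[id(u)]
        for s in u.children:
            if s is node:
                continue
            acc = acc * (self._P[id(s)] @ self._up[id(s)])
            sc = sc + self._up_scale[id(s)]
        up = self._up[id(node)]
        sc = sc + self._up_scale[id(node)]
        logw = np.log(self.site_rates.weights)[:, None]
        rates = self.site_rates.rates

        def f(t: float) -> float:
            P = self.model.transition_stack(t, rates)
            L = (acc * (P @ up)).sum(axis=1)
            L = np.clip(L, 1e-300, None)
            a = np.log(L) + sc + logw
            amax = a.max(axis=0)
            ll = amax + np.log(np.exp(a - amax).sum(axis=0))
            return float(ll @ self.pattern_weights)

        return f


def log_likelihood(
    tree: PhyloTree,
    alignment: Alignment,
    model: M.RateMatrix,
    site_rates: M.SiteRateModel | None = None,
) -> LikelihoodResult:
    return LikelihoodEngine(tree, alignment, model, site_rates).result()


# ---------------------------------------------------------------------------
# Branch-length optimization


def optimize_branch_lengths(
    tree: PhyloTree,
    alignment: Alignment,
    model: M.RateMatrix,
    site_rates: M.SiteRateModel | None = None,
    tol: float = 1e-6,
    max_sweeps: int = 20,
) -> PhyloTree:
    """Coordinate-wise branch-length optimization (in place on a copy).

    Each sweep optimizes every branch in turn with a bounded scalar search on
    the single-branch likelihood profile; sweeps repeat until the total
    log-likelihood improves by less than ``tol``.  The log-likelihood never
    decreases at an accepted step.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    work = tree.copy()
    engine = LikelihoodEngine(work, alignment, model, site_rates)
    current = engine.log_likelihood()
    for _ in range(max_sweeps):
        start = current
        for node in work.postorder():
            if node.parent is None:
                continue
            f = engine.branch_profile(node)
            res = minimize_scalar(
                lambda t: -f(t), bounds=(BL_MIN, BL_MAX), method="bounded",
                options={"xatol": 1e-8},
            )
            cand_ll = -res.fun
            if cand_ll > current:
                node.length = float(np.clip(res.x, BL_MIN, BL_MAX))
                current = cand_ll
            engine.invalidate()  # lengths (possibly) changed; recompute lazily
        if current - start < tol:
            break
    return work


# ---------------------------------------------------------------------------
# Pairwise ML distances and neighbor joining


def ml_distance(
    seq_a,
    seq_b,
    model: M.RateMatrix,
    site_rates: M.SiteRateModel | None = None,
) -> float:
    """Pairwise ML distance by 1-D optimization, capped at BL_MAX."""
    site_rates = site_rates or M.uniform_rates()
    mat = encode_alignment(Alignment([seq_a, seq_b]), model.states)
    ok = (mat[0] >= 0) & (mat[1] >= 0)
    if not ok.any():
        raise LikelihoodError(
            f"no overlapping sites between {seq_a.identifier!r} and {seq_b.identifier!r}"
        )
    a, b = mat[0][ok], mat[1][ok]
    pairs, counts = np.unique(np.stack([a, b]), axis=1, return_counts=True)
    pi = model.frequencies

    def negll(t: float) -> float:
        L = np.zeros(pairs.shape[1])
        for w, r in zip(site_rates.weights, site_rates.rates):
            P = model.transition_matrix(t, r)
            L += w * pi[pairs[0]] * P[pairs[0], pairs[1]]
        return -float(np.log(np.clip(L, 1e-300, None)) @ counts)

    res = minimize_scalar(
        negll, bounds=(BL_MIN, BL_MAX), method="bounded", options={"xatol": 1e-8}
    )
    return float(res.x)


def ml_distance_matrix(
    alignment: Alignment,
    model: M.RateMatrix,
    site_rates: M.SiteRateModel | None = None,
) -> np.ndarray:
    n = alignment.n_taxa
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = ml_distance(
                alignment.sequences[i], alignment.sequences[j], model, site_rates
            )
    return d


def nj_tree(distances: np.ndarray, identifiers: list[str]) -> PhyloTree:
    """Neighbor-joining tree (negative branch-length estimates clamped to 0)."""
    dm = DistanceMatrix(distances, ids=list(identifiers))
    skt = _skbio_nj(dm)
    buf = io.StringIO()
    skt.write(buf, format="newick")
    tree = parse_newick(buf.getvalue())
    for node in tree.postorder():
        if node.length < 0:
            node.length = 0.0
    return unroot(tree)


def unroot(tree: PhyloTree) -> PhyloTree:
    """Collapse a bifurcating root into a basal trifurcation (no-op otherwise)."""
    t = tree.copy()
    root = t.root
    while len(root.children) == 2 and any(not c.is_leaf for c in root.children):
        internal = next(c for c in root.children if not c.is_leaf)
        other = next(c for c in root.children if c is not internal)
        other.length += internal.length
        root.children.remove(internal)
        for gc in internal.children:
            root.add_child(gc)
        root.label = root.label or internal.label
        if len(root.children) >= 3:
            break
    t.rooted = False
    return t


# ---------------------------------------------------------------------------
# NNI search


def _internal_edges(tree: PhyloTree) -> list[Node]:
    """Internal edges as their child-end nodes (unrooted representation)."""
    return [
        n
        for n in tree.postorder()
        if n.parent is not None and not n.is_leaf and not n.parent.is_leaf
    ]


def _swap_subtrees(a: Node, b: Node) -> None:
    pa, pb = a.parent, b.parent
    ia, ib = pa.children.index(a), pb.children.index(b)
    pa.children[ia], pb.children[ib] = b, a
    a.parent, b.parent = pb, pa


def _nni_candidates(tree: PhyloTree):
    """Yield (edge_child, child_of_edge, sibling) triples describing the two
    NNI rearrangements at every internal edge."""
    for v in _internal_edges(tree):
        u = v.parent
        sibs = [c for c in u.children if c is not v]
        s = sibs[0]
        for a in v.children[:2]:
            yield v, a, s


def nni_search(
    start: PhyloTree,
    alignment: Alignment,
    model: M.RateMatrix,
    site_rates: M.SiteRateModel | None = None,
    max_rounds: int = 20,
    bl_tol: float = 1e-4,
) -> LikelihoodResult:
    """NNI hill-climbing with branch-length re-optimization.

    Candidate rearrangements are scored with the central and four incident
    branch lengths re-optimized; the best strictly improving move (beyond a
    1e-9 tie tolerance) is accepted and all branch lengths re-optimized
    before the next round.  Deterministic given its inputs.
    """
    tree = optimize_branch_lengths(unroot(start), alignment, model, site_rates, tol=bl_tol)
    current = LikelihoodEngine(tree, alignment, model, site_rates).log_likelihood()
    for _ in range(max_rounds):
        best_ll, best_move = current, None
        for v, a, s in _nni_candidates(tree):
            cand = tree.copy()
            # locate corresponding nodes in the copy by postorder position
            pos = {id(n): i for i, n in enumerate(tree.postorder())}
            cnodes = cand.postorder()
            cv, ca, cs = cnodes[pos[id(v)]], cnodes[pos[id(a)]], cnodes[pos[id(s)]]
            _swap_subtrees(ca, cs)
            engine = LikelihoodEngine(cand, alignment, model, site_rates)
            local = [cv, ca, cs] + list(cv.children) + [
                c for c in cv.parent.children if c is not cv
            ]
            ll = engine.log_likelihood()
            for nd in local:
                if nd.parent is None:
                    continue
                f = engine.branch_profile(nd)
                res = minimize_scalar(
                    lambda t: -f(t), bounds=(BL_MIN, BL_MAX), method="bounded",
                    options={"xatol": 1e-5},
                )
                if -res.fun > ll:
                    nd.length = float(np.clip(res.x, BL_MIN, BL_MAX))
                    ll = -res.fun
                engine.invalidate()
            if ll > best_ll + 1e-9:
                best_ll, best_move = ll, (v, a, s)
        if best_move is None:
            break
        v, a, s = best_move
        _swap_subtrees(a, s)
        tree = optimize_branch_lengths(tree, alignment, model, site_rates, tol=bl_tol)
        current = LikelihoodEngine(tree, alignment, model, site_rates).log_likelihood()
    return LikelihoodEngine(tree, alignment, model, site_rates).result()


def search_ml_tree(
    alignment: Alignment,
    model: M.RateMatrix,
    site_rates: M.SiteRateModel | None = None,
    max_rounds: int = 20,
) -> LikelihoodResult:
    """NJ starting tree (from pairwise ML distances) followed by NNI search."""
    d = ml_distance_matrix(alignment, model, site_rates)
    start = nj_tree(d, alignment.identifiers)
    return nni_search(start, alignment, model, site_rates, max_rounds=max_rounds)


# ---------------------------------------------------------------------------
# Bootstrap


@dataclass
class BootstrapSupport:
    supports: dict[frozenset, float]  # bipartition -> percent
    n_replicates: int
    best_tree: PhyloTree

    def annotate(self) -> PhyloTree:
        """Copy of the best tree with supports as internal-node labels."""
        t = self.best_tree.copy()
        all_leaves = set(t.leaf_labels())
        ref = min(all_leaves)
        below: dict[int, set] = {}
        for n in t.postorder():
            below[id(n)] = (
                {n.label} if n.is_leaf
                else set().union(*(below[id(c)] for c in n.children))
            )
        for n in t.postorder():
            if n.is_leaf or n.parent is None:
                continue
            side = below[id(n)]
            key = frozenset(side if ref not in side else all_leaves - side)
            if key in self.supports:
                n.label = f"{self.supports[key]:.0f}"
        return t


def bootstrap_support(
    alignment: Alignment,
    model: M.RateMatrix,
    site_rates: M.SiteRateModel | None = None,
    n_replicates: int = 100,
    seed: int = 0,
    best_tree: PhyloTree | None = None,
) -> BootstrapSupport:
    """Nonparametric bootstrap: resample columns, rerun the full search, and
    report the percentage of replicate trees containing each bipartition of
    the best tree."""
    if n_replicates < 1:
        raise ValueError("need at least one bootstrap replicate")
    if best_tree is None:
        best_tree = search_ml_tree(alignment, model, site_rates).tree
    target = best_tree.bipartitions()
    counts = {b: 0 for b in target}
    rng = np.random.default_rng(seed)
    n_cols = alignment.n_columns
    for _ in range(n_replicates):
        cols = [int(c) + 1 for c in rng.integers(0, n_cols, size=n_cols)]
        rep = alignment.take_columns(cols)
        rep_tree = search_ml_tree(rep, model, site_rates).tree
        rep_bip = rep_tree.bipartitions()
        for b in target:
            if b in rep_bip:
                counts[b] += 1
    supports = {b: 100.0 * c / n_replicates for b, c in counts.items()}
    return BootstrapSupport(supports, n_replicates, best_tree)


# ---------------------------------------------------------------------------
# AIC model selection


@dataclass
class ModelSpec:
    """A named substitution-model configuration such as 'WAG+F+G' or
    'GTR+I+G'."""

    name: str

    @property
    def parts(self) -> list[str]:
        return self.name.upper().split("+")

    @property
    def base(self) -> str:
        return self.parts[0]

    @property
    def has_gamma(self) -> bool:
        return "G" in self.parts[1:]

    @property
    def has_invariant(self) -> bool:
        return "I" in self.parts[1:]

    @property
    def empirical_freqs(self) -> bool:
        return "F" in self.parts[1:]

    @property
    def n_free_parameters(self) -> int:
        if self.base == "WAG":
            k = 19 if self.empirical_freqs else 0
        elif self.base == "GTR":
            k = 5 + 3
        else:
            raise ValueError(f"unknown model {self.name!r}")
        if self.has_gamma:
            k += 1
        if self.has_invariant:
            k += 1
        return k


def _fit_candidate(spec: ModelSpec, alignment: Alignment, tree: PhyloTree):
    """Optimize a candidate's free parameters on the fixed tree; return
    (log-likelihood, fitted model, fitted site rates)."""

    def build(theta):
        pos = 0
        if spec.base == "WAG":
            freqs = M.empirical_aa_frequencies(alignment) if spec.empirical_freqs else None
            model = M.build_empirical_aa("WAG", freqs)
        else:
            ex = np.exp(theta[pos : pos + 5]) if len(theta) else np.ones(5)
            pos += 5
            counts = np.full(4, 0.1)
            idx = {s: i for i, s in enumerate(M.NT_STATES)}
            for s in alignment.sequences:
                for ch in s.residues:
                    if ch in idx:
                        counts[idx[ch]] += 1
            model = M.build_gtr(np.append(ex, 1.0), counts / counts.sum())
        alpha = np.exp(theta[pos]) if spec.has_gamma else None
        pos += 1 if spec.has_gamma else 0
        pinv = 1 / (1 + np.exp(-theta[pos])) if spec.has_invariant else 0.0
        if spec.has_gamma:
            rates = M.discrete_gamma(alpha, 4, p_invariant=pinv)
        elif spec.has_invariant:
            rates = M.discrete_gamma(1e6, 1)
            rates = M.SiteRateModel(
                np.array([0.0, 1.0 / (1.0 - pinv)]),
                np.array([pinv, 1.0 - pinv]),
                p_invariant=pinv,
            )
        else:
            rates = M.uniform_rates()
        return model, rates

    n_theta = (5 if spec.base == "GTR" else 0) + int(spec.has_gamma) + int(
        spec.has_invariant
    )

    def negll(theta):
        model, rates = build(theta)
        try:
            return -LikelihoodEngine(tree, alignment, model, rates).log_likelihood()
        except (M.ModelError, FloatingPointError):
            return 1e12

    if n_theta == 0:
        theta = np.array([])
    else:
        res = minimize(
            negll, np.zeros(n_theta), method="Nelder-Mead",
            options={"xatol": 1e-3, "fatol": 1e-4, "maxiter": 200 * n_theta},
        )
        theta = res.x
    model, rates = build(theta)
    ll = LikelihoodEngine(tree, alignment, model, rates).log_likelihood()
    return ll, model, rates


def select_model_aic(
    alignment: Alignment,
    candidates: list[str] | None = None,
    tree: PhyloTree | None = None,
):
    """Rank candidate model specs by AIC = 2k - 2 lnL on a fixed NJ tree.

    Returns a pandas DataFrame sorted by AIC ascending, with columns
    (model, k, log_likelihood, aic).
    """
    import pandas as pd

    if candidates is None:
        candidates = (
            ["WAG", "WAG+G", "WAG+F+G"]
            if alignment.alphabet == "aa"
            else ["GTR", "GTR+G", "GTR+I+G"]
        )
    if not candidates:
        raise ValueError("candidate list is empty")
    if tree is None:
        base = (
            M.build_empirical_aa("WAG")
            if alignment.alphabet == "aa"
            else M.jukes_cantor()
        )
        d = ml_distance_matrix(alignment, base)
        tree = nj_tree(d, alignment.identifiers)
        tree = optimize_branch_lengths(tree, alignment, base, tol=1e-3)
    rows = []
    for name in candidates:
        spec = ModelSpec(name)
        ll, _, _ = _fit_candidate(spec, alignment, tree)
        k = spec.n_free_parameters
        rows.append({"model": name, "k": k, "log_likelihood": ll, "aic": 2 * k - 2 * ll})
    return pd.DataFrame(rows).sort_values("aic", kind="stable").reset_index(drop=True)
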