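"""Divergence-time estimation: phylogram -> chronogram with one calibration.

Two estimators are provided.  ``date_clock`` is a strict-clock (Langley-Fitch
style) estimator: node ages and a single global rate maximize a Poisson
likelihood of per-branch substitution counts.  ``date_nprs`` is nonparametric
rate smoothing: ages minimize the sum of |rate difference|^p between each
branch and its daughter branches.  Both fix the age of one calibrated MRCA
and keep leaves at age zero.

Ages are parameterized without explicit constraints: nodes on the path from
the calibrated node to the root carry positive age increments, and every
other internal node carries a fraction of its parent's age, so parent >=
child >= 0 holds by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .seqio import Node, PhyloTree, TreeError


@dataclass(frozen=True)
class Calibration:
    """Fix the age (Myr) of the MRCA of the named taxa."""

    mrca_of: frozenset
    age: float

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError("calibration age must be positive")


@dataclass
class Chronogram:
    tree: PhyloTree                      # ages set on every node
    rate: float | None = None            # strict-clock rate (subs/site/Myr)
    objective: float | None = None       # NPRS objective at the solution

    def branch_rates(self) -> dict[str, float]:
        """Implied per-branch rate = branch length / duration, keyed by the
        child node's label."""
        out = {}
        for n in self.tree.postorder():
            if n.parent is None:
                continue
            d = max(n.parent.age - n.age, 1e-12)
            out[n.label] = n.length / d
        return out


def node_age(chronogram: Chronogram, mrca_of) -> float:
    """Age (Myr) of the most recent common ancestor of the given taxa."""
    node = chronogram.tree.mrca(set(mrca_of))
    return float(node.age)


# ---------------------------------------------------------------------------
# Shared age parameterization


class _AgeParam:
    """Maps an unconstrained parameter vector to a valid age assignment."""

    def __init__(self, tree: PhyloTree, calibration: Calibration):
        self.tree = tree
        self.cal_node = tree.mrca(calibration.mrca_of)
        if self.cal_node.is_leaf:
            raise TreeError("calibration node is a leaf; calibrate an MRCA")
        self.cal_age = calibration.age
        self.ancestors: list[Node] = []  # path cal_node.parent ... root
        n = self.cal_node.parent
        while n is not None:
            self.ancestors.append(n)
            n = n.parent
        anc_ids = {id(a) for a in self.ancestors}
        self.free: list[Node] = [
            n
            for n in tree.preorder()
            if not n.is_leaf and n is not self.cal_node and id(n) not in anc_ids
        ]
        self.n_params = len(self.ancestors) + len(self.free)

    def initial(self, jitter_rng: np.random.Generator | None = None) -> np.ndarray:
        """Start from ages proportional to mean root-to-leaf path depths,
        scaled so the calibration node hits its age exactly."""
        mean_depth: dict[int, float] = {}
        for n in self.tree.postorder():
            if n.is_leaf:
                mean_depth[id(n)] = 0.0
            else:
                mean_depth[id(n)] = float(
                    np.mean([mean_depth[id(c)] + c.length for c in n.children])
                )
        scale = self.cal_age / max(mean_depth[id(self.cal_node)], 1e-9)
        ages = {i: d * scale for i, d in mean_depth.items()}
        theta = []
        prev = self.cal_age
        for a in self.ancestors:
            inc = max(ages[id(a)] - prev, 1e-6 * self.cal_age)
            theta.append(np.log(inc))
            prev = prev + inc
            ages[id(a)] = prev
        for n in self.free:
            pa = ages[id(n.parent)]
            frac = min(max(ages[id(n)] / max(pa, 1e-12), 1e-4), 1 - 1e-4)
            theta.append(np.log(frac / (1 - frac)))
        theta = np.asarray(theta)
        if jitter_rng is not None:
            theta = theta + jitter_rng.normal(0.0, 0.5, size=theta.shape)
        return theta

    def ages(self, theta: np.ndarray) -> dict[int, float]:
        ages: dict[int, float] = {id(self.cal_node): self.cal_age}
        for leaf in self.tree.leaves():
            ages[id(leaf)] = 0.0
        prev = self.cal_age
        for i, a in enumerate(self.ancestors):
            prev = prev + np.exp(theta[i])
            ages[id(a)] = prev
        off = len(self.ancestors)
        for j, n in enumerate(self.free):  # preorder: parent age already set
            ages[id(n)] = float(expit(theta[off + j])) * ages[id(n.parent)]
        return ages

    def apply(self, theta: np.ndarray) -> None:
        ages = self.ages(theta)
        for n in self.tree.postorder():
            n.age = float(ages[id(n)])


def _finalize(tree: PhyloTree, calibration: Calibration) -> None:
    tree.check_age_invariants()
    cal = tree.mrca(calibration.mrca_of)
    if abs(cal.age - calibration.age) > 1e-6 * calibration.age:
        raise TreeError("calibration age not honoured by the optimizer")


# ---------------------------------------------------------------------------
# Strict clock


def _edge_groups(tree: PhyloTree) -> list[list[Node]]:
    """Branches as observation groups for dating.

    When the root has exactly two children, the position of the root along
    the branch joining them is not identified by a reversible model, so the
    two basal branches are pooled into one observation (summed length, summed
    duration) — the standard treatment of the root branch in rate smoothing
    and clock dating.
    """
    groups: list[list[Node]] = []
    root = tree.root
    basal = root.children if len(root.children) == 2 else []
    if basal:
        groups.append(list(basal))
    for n in tree.postorder():
        if n.parent is None or n in basal:
            continue
        groups.append([n])
    return groups


def date_clock(
    tree: PhyloTree, calibration: Calibration, n_sites: int
) -> Chronogram:
    """Strict-clock dating by Poisson likelihood of branch substitution counts.

    Branch lengths (subs/site) times ``n_sites`` act as observed counts with
    expectation rate * duration * n_sites; the global rate and all node ages
    are estimated jointly.
    """
    if n_sites <= 0:
        raise ValueError("n_sites must be positive")
    if not tree.rooted:
        raise TreeError("strict-clock dating needs a rooted tree")
    work = tree.copy()
    param = _AgeParam(work, calibration)
    groups = _edge_groups(work)
    x = np.array([sum(n.length for n in g) * n_sites for g in groups])

    def negll(full: np.ndarray) -> float:
        theta, lograte = full[:-1], full[-1]
        ages = param.ages(theta)
        d = np.array(
            [
                max(sum(ages[id(n.parent)] - ages[id(n)] for n in g), 1e-12)
                for g in groups
            ]
        )
        mu = np.exp(lograte) * d * n_sites
        mu = np.clip(mu, 1e-12, None)
        return float(np.sum(mu - x * np.log(mu)))

    theta0 = param.initial()
    ages0 = param.ages(theta0)
    edges = [n for n in work.postorder() if n.parent is not None]
    d0 = sum(max(ages0[id(n.parent)] - ages0[id(n)], 1e-12) for n in edges)
    rate0 = max(sum(n.length for n in edges) / max(d0, 1e-12), 1e-12)
    full0 = np.append(theta0, np.log(rate0))
    res = minimize(negll, full0, method="L-BFGS-B", options={"maxiter": 2000, "ftol": 1e-14})
    best = res.x if res.fun <= negll(full0) else full0
    param.apply(best[:-1])
    _finalize(work, calibration)
    return Chronogram(work, rate=float(np.exp(best[-1])))


# ---------------------------------------------------------------------------
# Nonparametric rate smoothing


def nprs_objective(
    tree: PhyloTree, exponent: float = 2.0, root_rates: str = "mean"
) -> float:
    """Rate-smoothing objective at the current node ages.

    Sum over non-root internal nodes of |parent-branch rate minus child-branch
    rate|^exponent.  The root, which has no parent branch, contributes a term
    per ``root_rates``: "mean" penalizes each basal branch's deviation from
    the mean basal rate (the classical formulation); "pooled" gives the basal
    branches one shared rate (summed length over summed duration) and no root
    term — appropriate when the tree was midpoint-rooted on an outgroup
    branch, where the basal split of length is arbitrary.
    """
    rate: dict[int, float] = {}
    basal = tree.root.children
    if root_rates == "pooled" and len(basal) == 2:
        length = sum(n.length for n in basal)
        dur = max(sum(n.parent.age - n.age for n in basal), 1e-12)
        for n in basal:
            rate[id(n)] = length / dur
    for n in tree.postorder():
        if n.parent is None or id(n) in rate:
            continue
        rate[id(n)] = n.length / max(n.parent.age - n.age, 1e-12)
    total = 0.0
    for n in tree.postorder():
        if n.parent is None or n.is_leaf:
            continue
        rp = rate[id(n)]
        for c in n.children:
            total += abs(rp - rate[id(c)]) ** exponent
    if root_rates == "mean" and len(basal) >= 2:
        rs = [rate[id(c)] for c in basal]
        m = sum(rs) / len(rs)
        total += sum(abs(r - m) ** exponent for r in rs)
    return total


def date_nprs(
    tree: PhyloTree,
    calibration: Calibration,
    smoothing_exponent: float = 2.0,
    n_starts: int = 5,
    seed: int = 0,
    root_rates: str = "mean",
) -> Chronogram:
    """Nonparametric rate smoothing with multistart local optimization.

    The first start is the strict-clock-style initialization (ages
    proportional to mean path depths); the remaining starts jitter it.  The
    best objective wins, so the result is never worse than the clocklike
    solution it starts from.
    """
    if not tree.rooted:
        raise TreeError("rate smoothing needs a rooted tree")
    work = tree.copy()
    param = _AgeParam(work, calibration)

    def obj(theta: np.ndarray) -> float:
        param.apply(theta)
        return nprs_objective(work, smoothing_exponent, root_rates)

    best_theta, best_val = None, np.inf
    for s in range(n_starts):
        rng = None if s == 0 else np.random.default_rng([seed, s])
        theta0 = param.initial(jitter_rng=rng)
        res = minimize(obj, theta0, method="Nelder-Mead",
                       options={"maxiter": 20000, "xatol": 1e-10, "fatol": 1e-14})
        for cand in (res.x, theta0):
            v = obj(cand)
            if v < best_val:
                best_val, best_theta = v, cand.copy()
    param.apply(best_theta)
    _finalize(work, calibration)
    return Chronogram(work, objective=float(best_val))
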