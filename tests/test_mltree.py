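"""Likelihood engine, branch-length optimization, NJ/NNI search, bootstrap
and AIC model choice."""

import numpy as np
import pytest

from asrpipe import models as M
from asrpipe import mltree as T
from asrpipe import synth
from asrpipe.seqio import Alignment, Node, PhyloTree, Sequence, parse_newick

from conftest import (
    brute_force_log_likelihood,
    random_alignment,
    random_binary_tree,
    random_model,
    random_site_rates,
)


class TestPruningLikelihood:
    def test_single_leaf_likelihood_is_stationary_frequency(self, wag):
        root = Node("r")
        root.add_child(Node("a", 1e-9))
        tree = PhyloTree(root)
        aln = Alignment([Sequence("a", "K", "aa")])
        res = T.log_likelihood(tree, aln, wag)
        k = wag.state_index("K")
        assert res.log_likelihood == pytest.approx(np.log(wag.frequencies[k]), abs=1e-6)

    def test_two_leaf_factorization(self, jc):
        # reversibility: L = pi_a * P_ab(t1 + t2)
        tree = parse_newick("(a:0.12,b:0.3);")
        aln = Alignment([Sequence("a", "A", "nt"), Sequence("b", "G", "nt")])
        res = T.log_likelihood(tree, aln, jc)
        expect = 0.25 * jc.transition_matrix(0.42)[0, 2]
        assert res.log_likelihood == pytest.approx(np.log(expect), abs=1e-12)

    @pytest.mark.parametrize("alphabet", ["aa", "nt", "codon"])
    def test_pruning_equals_enumeration(self, alphabet):
        rng = np.random.default_rng(42)
        for _ in range(3):
            tree = random_binary_tree(int(rng.integers(3, 5)), rng)
            model = random_model(alphabet, rng)
            rates = random_site_rates(rng)
            aln = random_alignment(tree, alphabet, 3, rng)
            got = T.log_likelihood(tree, aln, model, rates).per_site_log_likelihoods
            want = brute_force_log_likelihood(tree, aln, model, rates)
            assert np.abs(got - want).max() < 1e-12

    def test_pattern_compression_preserves_likelihood(self, jc):
        tree = parse_newick("((a:0.1,b:0.2):0.1,(c:0.3,d:0.1):0.2);")
        rng = np.random.default_rng(3)
        cols = ["ACGT"[rng.integers(4)] * 2 + "AC"[rng.integers(2)] * 2
                for _ in range(40)]
        # alignment with many repeated patterns
        rows = ["".join(c[i] for c in cols) for i in range(4)]
        aln = Alignment([Sequence(x, r, "nt") for x, r in zip("abcd", rows)])
        eng = T.LikelihoodEngine(tree, aln, jc)
        assert eng.n_patterns < aln.n_columns
        total = eng.log_likelihood()
        assert total == pytest.approx(eng.per_site_log_likelihoods().sum(), abs=1e-10)

    def test_likelihood_invariant_to_virtual_root_placement(self, wag):
        rng = np.random.default_rng(5)
        tree = random_binary_tree(5, rng)
        aln = random_alignment(tree, "aa", 6, rng)
        ll1 = T.log_likelihood(tree, aln, wag).log_likelihood
        ll2 = T.log_likelihood(T.unroot(tree), aln, wag).log_likelihood
        assert ll1 == pytest.approx(ll2, abs=1e-9)

    def test_leaf_alignment_mismatch_names_offenders(self, jc):
        tree = parse_newick("(a:0.1,b:0.1);")
        aln = Alignment([Sequence("a", "A", "nt"), Sequence("c", "A", "nt")])
        with pytest.raises(T.LikelihoodError, match="c"):
            T.log_likelihood(tree, aln, jc)

    def test_per_site_values_sum_to_total(self, wag):
        rng = np.random.default_rng(9)
        tree = random_binary_tree(4, rng)
        aln = random_alignment(tree, "aa", 20, rng)
        res = T.log_likelihood(tree, aln, wag, M.discrete_gamma(0.8, 4))
        assert res.log_likelihood == pytest.approx(
            res.per_site_log_likelihoods.sum(), abs=1e-8
        )


class TestBranchLengthOptimization:
    def test_two_leaf_simulation_recovery(self, jc):
        root = Node("r")
        root.add_child(Node("a", 0.1))
        root.add_child(Node("b", 0.1))
        tree = PhyloTree(root)
        aln, _ = synth.simulate_sites(tree, jc, n_sites=10_000, seed=4)
        start = tree.copy()
        for n in start.postorder():
            if n.parent is not None:
                n.length = 0.5
        opt = T.optimize_branch_lengths(start, aln, jc)
        total = sum(n.length for n in opt.postorder() if n.parent is not None)
        assert total == pytest.approx(0.2, rel=0.10)

    def test_fixed_point_and_monotonicity(self, wag):
        rng = np.random.default_rng(8)
        tree = random_binary_tree(5, rng)
        aln = random_alignment(tree, "aa", 30, rng, missing_prob=0.0)
        before = T.log_likelihood(tree, aln, wag).log_likelihood
        opt = T.optimize_branch_lengths(tree, aln, wag, tol=1e-6)
        after = T.log_likelihood(opt, aln, wag).log_likelihood
        assert after >= before
        again = T.optimize_branch_lengths(opt, aln, wag, tol=1e-6)
        assert T.log_likelihood(again, aln, wag).log_likelihood - after < 1e-3


class TestDistancesAndNj:
    def test_identical_sequences_have_near_zero_distance(self, jc):
        a = Sequence("a", "ACGTACGTACGTACGTACGT", "nt")
        b = Sequence("b", "ACGTACGTACGTACGTACGT", "nt")
        assert T.ml_distance(a, b, jc) < 1e-5

    def test_jc_closed_form_distance(self, jc):
        # 10% observed differences -> -(3/4) ln(1 - 4/3 * 0.10)
        base = "ACGT" * 50
        mutated = list(base)
        for i in range(0, 200, 10):
            mutated[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[i]]
        d = T.ml_distance(Sequence("a", base, "nt"), Sequence("b", "".join(mutated), "nt"), jc)
        assert d == pytest.approx(-0.75 * np.log(1 - 4 / 3 * 0.10), rel=1e-3)

    def test_no_overlap_is_error(self, jc):
        a = Sequence("a", "AC--", "nt")
        b = Sequence("b", "--GT", "nt")
        with pytest.raises(T.LikelihoodError):
            T.ml_distance(a, b, jc)

    def test_nj_recovers_additive_topology(self):
        # additive 4-taxon metric for ((a,b),(c,d))
        d = np.array(
            [
                [0.0, 0.3, 0.9, 1.0],
                [0.3, 0.0, 1.0, 1.1],
                [0.9, 1.0, 0.0, 0.3],
                [1.0, 1.1, 0.3, 0.0],
            ]
        )
        tree = T.nj_tree(d, ["a", "b", "c", "d"])
        assert frozenset({"c", "d"}) in tree.bipartitions() or frozenset(
            {"a", "b"}
        ) in tree.bipartitions()

    def test_nj_branch_lengths_nonnegative(self):
        rng = np.random.default_rng(2)
        n = 6
        x = rng.uniform(0, 1, (n, 2))
        d = np.sqrt(((x[:, None] - x[None, :]) ** 2).sum(-1))
        tree = T.nj_tree(d, [f"t{i}" for i in range(n)])
        assert all(nd.length >= 0 for nd in tree.postorder())


class TestNniSearch:
    def test_three_leaf_tree_returned_unchanged(self, jc):
        tree = parse_newick("(a:0.1,b:0.1,c:0.1);")
        aln = Alignment([Sequence(x, "ACGT", "nt") for x in "abc"])
        res = T.nni_search(tree, aln, jc)
        assert res.tree.bipartitions() == set()

    def test_recovers_generating_topology_from_wrong_start(self, jc):
        true = parse_newick("((a:0.1,b:0.1):0.1,(c:0.1,d:0.1):0.1);")
        aln, _ = synth.simulate_sites(true, jc, n_sites=2000, seed=10)
        wrong = parse_newick("((a:0.1,c:0.1):0.1,(b:0.1,d:0.1):0.1);")
        res = T.nni_search(wrong, aln, jc)
        got = res.tree.bipartitions()
        assert frozenset({"c", "d"}) in got or frozenset({"a", "b"}) in got

    def test_hill_climbing_never_decreases_likelihood(self, jc):
        true = parse_newick("((a:0.2,b:0.2):0.2,(c:0.2,d:0.2):0.2);")
        aln, _ = synth.simulate_sites(true, jc, n_sites=300, seed=1)
        start = parse_newick("((a:0.3,c:0.3):0.3,(b:0.3,d:0.3):0.3);")
        before = T.log_likelihood(T.unroot(start), aln, jc).log_likelihood
        res = T.nni_search(start, aln, jc)
        assert res.log_likelihood >= before - 1e-9


class TestBootstrap:
    def _informative_alignment(self):
        """Many clean synapomorphies for every clade of ((a,b),(c,d),(e,f)),
        over a constant background that keeps divergence moderate."""
        blocks = {  # one diagnostic block per clade of the unrooted tree
            "a": "AAAA" "CCCC" "GGGG",
            "b": "AAAA" "CCCC" "GGGG",
            "c": "TTTT" "CCCC" "AAAA",
            "d": "TTTT" "CCCC" "AAAA",
            "e": "TTTT" "AAAA" "GGGG",
            "f": "TTTT" "AAAA" "GGGG",
        }
        rows = {}
        for i, (k, v) in enumerate(blocks.items()):
            # taxon-specific noise columns keep pairwise distances positive
            noise = "".join("ACGT"[(i + j) % 4] for j in range(6))
            rows[k] = v * 4 + "G" * 60 + noise
        return Alignment([Sequence(k, v, "nt") for k, v in rows.items()])

    def test_perfectly_informative_alignment_gets_full_support(self, jc):
        aln = self._informative_alignment()
        bs = T.bootstrap_support(aln, jc, n_replicates=20, seed=3)
        assert bs.supports  # non-trivial edges exist
        assert all(v == 100.0 for v in bs.supports.values())

    def test_supports_within_bounds_and_deterministic(self, jc):
        aln = self._informative_alignment()
        b1 = T.bootstrap_support(aln, jc, n_replicates=10, seed=7)
        b2 = T.bootstrap_support(aln, jc, n_replicates=10, seed=7)
        assert b1.supports == b2.supports
        assert all(0 <= v <= 100 for v in b1.supports.values())


class TestModelSelection:
    def test_parameter_census(self):
        assert T.ModelSpec("GTR+I+G").n_free_parameters == 10
        assert T.ModelSpec("WAG").n_free_parameters == 0
        assert T.ModelSpec("WAG+F+G").n_free_parameters == 20
        assert T.ModelSpec("GTR").n_free_parameters == 8

    def test_duplicate_candidates_get_identical_aic(self, jc):
        tree = parse_newick("((a:0.1,b:0.1):0.1,(c:0.1,d:0.1):0.1);")
        aln, _ = synth.simulate_sites(tree, jc, n_sites=200, seed=2)
        table = T.select_model_aic(aln, ["GTR", "GTR"], tree=tree)
        assert table["aic"].iloc[0] == pytest.approx(table["aic"].iloc[1], abs=1e-6)

    def test_gamma_variant_wins_under_strong_heterogeneity(self, jc):
        tree = parse_newick(
            "(((a:0.4,b:0.4):0.2,(c:0.4,d:0.4):0.2):0.2,(e:0.4,f:0.4):0.4);"
        )
        aln, _ = synth.simulate_sites(
            tree, jc, M.discrete_gamma(0.3, 4), n_sites=800, seed=6
        )
        table = T.select_model_aic(aln, ["GTR", "GTR+G"], tree=tree)
        assert table.iloc[0]["model"] == "GTR+G"
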