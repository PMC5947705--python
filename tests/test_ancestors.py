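"""Marginal ancestral reconstruction, gap parsimony and confidence metrics."""

import numpy as np
import pytest

from asrpipe import models as M
from asrpipe import synth
from asrpipe.ancestors import (
    PosteriorTable,
    confidence_metrics,
    infer_ancestral_gaps,
    map_sequence,
    marginal_posteriors,
)
from asrpipe.seqio import Alignment, Node, PhyloTree, Sequence, parse_newick

from conftest import (
    brute_force_marginal,
    random_alignment,
    random_binary_tree,
    random_model,
    random_site_rates,
)


class TestMarginalPosteriors:
    def test_star_tree_of_identical_leaves_is_certain(self, wag):
        root = Node("r")
        for x in "abcd":
            root.add_child(Node(x, 1e-6))
        tree = PhyloTree(root)
        aln = Alignment([Sequence(x, "A", "aa") for x in "abcd"])
        post = marginal_posteriors(tree, aln, wag, node=root)
        a = wag.state_index("A")
        assert post.probabilities[0, a] >= 0.999

    @pytest.mark.parametrize("alphabet", ["aa", "nt", "codon"])
    def test_matches_enumeration_at_every_internal_node(self, alphabet):
        rng = np.random.default_rng(17)
        tree = random_binary_tree(4, rng)
        model = random_model(alphabet, rng)
        rates = random_site_rates(rng)
        aln = random_alignment(tree, alphabet, 2, rng)
        for node in tree.internal_nodes():
            got = marginal_posteriors(tree, aln, model, rates, node).probabilities
            want = brute_force_marginal(tree, aln, model, rates, node)
            assert np.abs(got - want).max() < 1e-12

    def test_all_missing_column_returns_stationary(self, wag):
        tree = parse_newick("((a:0.1,b:0.1):0.1,(c:0.1,d:0.1):0.1);")
        aln = Alignment([Sequence(x, "-", "aa") for x in "abcd"])
        post = marginal_posteriors(tree, aln, wag, node=tree.root)
        assert np.abs(post.probabilities[0] - wag.frequencies).max() < 1e-9

    def test_leaf_node_rejected(self, wag):
        tree = parse_newick("(a:0.1,b:0.1);")
        aln = Alignment([Sequence(x, "K", "aa") for x in "ab"])
        with pytest.raises(ValueError, match="internal"):
            marginal_posteriors(tree, aln, wag, node=tree.leaves()[0])

    def test_posterior_calibration_on_simulations(self, wag):
        """Sites called with MAP posterior in [0.9, 1.0] should hold the true
        simulated state at least 85% of the time."""
        hits, total = 0, 0
        for seed in range(3):
            chron = synth.simulate_tree(16, root_age=1.0, seed=seed)
            tree = chron.tree.copy()
            # scale so branches average ~0.1 substitutions/site
            durs = [n.length for n in tree.postorder() if n.parent is not None]
            scale = 0.1 / np.mean(durs)
            for n in tree.postorder():
                n.length *= scale
            aln, states = synth.simulate_sites(tree, wag, n_sites=300, seed=seed)
            target = tree.root
            post = marginal_posteriors(tree, aln, wag, node=target)
            true_states = states[target.label]
            maps = post.map_indices
            conf = post.map_probabilities
            bin_mask = (conf >= 0.9) & (conf <= 1.0)
            hits += int((maps[bin_mask] == true_states[bin_mask]).sum())
            total += int(bin_mask.sum())
        assert total > 100
        assert hits / total >= 0.85


class TestMapSequence:
    def _uniform_table(self):
        probs = np.full((3, 20), 0.05)
        return PosteriorTable("n1", M.AA_STATES, probs)

    def test_uniform_posterior_takes_first_state_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            anc = map_sequence(self._uniform_table())
        assert anc.sequence.residues == "AAA"
        assert "tie" in caplog.text

    def test_masked_column_is_gap_regardless_of_posterior(self):
        probs = np.zeros((2, 20))
        probs[:, 5] = 1.0
        table = PosteriorTable("n1", M.AA_STATES, probs)
        anc = map_sequence(table, np.array([False, True]))
        assert anc.sequence.residues[1] == "-"

    def test_confidence_copied_from_map_probability(self):
        probs = np.zeros((2, 20))
        probs[0, 3] = 0.7
        probs[0, 4] = 0.3
        probs[1, 0] = 1.0
        table = PosteriorTable("n1", M.AA_STATES, probs)
        anc = map_sequence(table)
        assert anc.confidence.tolist() == [0.7, 1.0]

    def test_codon_table_gives_triplet_gaps(self):
        probs = np.zeros((2, 61))
        probs[:, 0] = 1.0
        table = PosteriorTable("n1", M.CODON_STATES, probs)
        anc = map_sequence(table, np.array([False, True]))
        assert anc.sequence.residues == "AAA---"


class TestAncestralGaps:
    def _tree16(self):
        chron = synth.simulate_tree(16, root_age=100.0, seed=0)
        return chron.tree

    def test_column_gapped_everywhere_is_ancestral_gap(self):
        tree = parse_newick("((a:1,b:1):1,(c:1,d:1):1);")
        aln = Alignment([Sequence(x, "-K", "aa") for x in "abcd"])
        mask = infer_ancestral_gaps(tree, aln, tree.root)
        assert mask.tolist() == [True, False]

    def test_single_gapped_leaf_of_sixteen_keeps_residue(self):
        tree = self._tree16()
        labels = tree.leaf_labels()
        seqs = [
            Sequence(lab, "-K" if lab == labels[0] else "KK", "aa")
            for lab in labels
        ]
        mask = infer_ancestral_gaps(tree, Alignment(seqs), tree.root)
        assert mask.tolist() == [False, False]

    def test_balanced_tie_resolves_to_present(self):
        tree = parse_newick("((a:1,b:1):1,(c:1,d:1):1);")
        aln = Alignment(
            [
                Sequence("a", "-", "aa"),
                Sequence("b", "-", "aa"),
                Sequence("c", "K", "aa"),
                Sequence("d", "K", "aa"),
            ]
        )
        mask = infer_ancestral_gaps(tree, aln, tree.root)
        assert mask.tolist() == [False]

    def test_clade_specific_deletion_reconstructed(self):
        tree = parse_newick("(((a:1,b:1):1,c:1):1,(d:1,(e:1,f:1):1):1);")
        aln = Alignment(
            [
                Sequence(x, "-K" if x in "abc" else "KK", "aa")
                for x in "abcdef"
            ]
        )
        node_abc = tree.mrca({"a", "b", "c"})
        node_def = tree.mrca({"d", "e", "f"})
        assert infer_ancestral_gaps(tree, aln, node_abc).tolist() == [True, False]
        assert infer_ancestral_gaps(tree, aln, node_def).tolist() == [False, False]


class TestConfidenceMetrics:
    def test_certain_tracks_give_unit_metrics(self):
        probs = np.zeros((4, 20))
        probs[:, 2] = 1.0
        t = PosteriorTable("n", M.AA_STATES, probs)
        m = confidence_metrics({"aa": t, "codon": t}, np.zeros(4, dtype=bool))
        assert m.per_track == {"aa": 1.0, "codon": 1.0}
        assert m.overall_average_posterior == 1.0

    def test_uniform_track_confidence_is_inverse_state_count(self):
        probs = np.full((5, 20), 0.05)
        t = PosteriorTable("n", M.AA_STATES, probs)
        m = confidence_metrics({"aa": t}, np.zeros(5, dtype=bool))
        assert m.per_track["aa"] == pytest.approx(0.05)

    def test_gap_columns_excluded(self):
        probs = np.full((2, 20), 0.05)
        probs[0] = 0.0
        probs[0, 0] = 1.0
        t = PosteriorTable("n", M.AA_STATES, probs)
        m = confidence_metrics({"aa": t}, np.array([False, True]))
        assert m.per_track["aa"] == 1.0
        assert m.n_columns_used == 1

    def test_metrics_match_recomputation_from_dump(self, wag):
        """Self-consistency: recompute the per-track mean from the posterior
        dump text and compare."""
        rng = np.random.default_rng(23)
        tree = random_binary_tree(5, rng)
        aln = random_alignment(tree, "aa", 12, rng)
        post = marginal_posteriors(tree, aln, wag, node=tree.root)
        m = confidence_metrics({"aa": post}, np.zeros(12, dtype=bool))
        best = {}
        for line in post.dump().splitlines()[1:]:
            node, col, state, p, is_map = line.split("\t")
            if is_map == "1":
                best[int(col)] = float(p)
        assert np.mean(list(best.values())) == pytest.approx(
            m.per_track["aa"], abs=1e-5
        )

    def test_all_gap_mask_is_error(self):
        probs = np.full((2, 20), 0.05)
        t = PosteriorTable("n", M.AA_STATES, probs)
        with pytest.raises(ValueError):
            confidence_metrics({"aa": t}, np.array([True, True]))
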