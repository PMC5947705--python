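"""Sequence/alignment/tree containers, format round-trips, the input filter
and outgroup rooting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asrpipe.seqio import (
    Alignment,
    Sequence,
    SequenceError,
    TreeError,
    filter_inputs,
    pairwise_identity_coverage,
    parse_newick,
    read_fasta,
    root_by_outgroup,
    write_fasta,
    write_newick,
)


class TestFasta:
    def test_parse_two_records(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nMK\n>b\nM-K\n")
        seqs = read_fasta(p, "aa")
        assert [s.identifier for s in seqs] == ["a", "b"]
        assert [len(s) for s in seqs] == [2, 3]

    def test_header_tokenized_at_whitespace(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a some description here\nMKV\n")
        assert read_fasta(p, "aa")[0].identifier == "a"

    def test_duplicate_identifier_rejected(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nMK\n>a\nMK\n")
        with pytest.raises(SequenceError, match="a"):
            read_fasta(p, "aa")

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text("")
        with pytest.raises(SequenceError):
            read_fasta(p, "aa")

    @settings(max_examples=25, deadline=None)
    @given(
        st.lists(
            st.text(alphabet="ACDEFGHIKLMNPQRSTVWYX-", min_size=1, max_size=80),
            min_size=1,
            max_size=6,
        )
    )
    def test_round_trip_is_identity(self, residues):
        import tempfile
        from pathlib import Path

        seqs = [Sequence(f"s{i}", r, "aa") for i, r in enumerate(residues)]
        with tempfile.TemporaryDirectory() as d:
            p = Path(d) / "rt.fasta"
            write_fasta(seqs, p)
            back = read_fasta(p, "aa")
        assert [(s.identifier, s.residues) for s in back] == [
            (s.identifier, s.residues) for s in seqs
        ]

    def test_alphabet_enforced(self):
        with pytest.raises(SequenceError):
            Sequence("bad", "MKJ", "aa")  # J is not an amino acid
        with pytest.raises(SequenceError):
            Sequence("bad", "ACGU", "nt")  # RNA letters rejected

    def test_codon_length_multiple_of_three(self):
        with pytest.raises(SequenceError):
            Sequence("bad", "ATGC", "codon")


class TestAlignment:
    def test_ragged_rejected(self):
        with pytest.raises(SequenceError, match="ragged"):
            Alignment([Sequence("a", "MK", "aa"), Sequence("b", "MKV", "aa")])

    def test_column_access_and_subset(self):
        aln = Alignment([Sequence("a", "MKV", "aa"), Sequence("b", "MRV", "aa")])
        assert aln.column(2) == ["K", "R"]
        assert aln.take_columns([3, 1]).sequences[0].residues == "VM"

    def test_all_gap_column_removable(self):
        aln = Alignment([Sequence("a", "M-K", "aa"), Sequence("b", "M-R", "aa")])
        assert aln.drop_all_gap_columns().n_columns == 2


class TestNewick:
    def test_rooted_parse(self):
        t = parse_newick("((a:1,b:1):1,c:2);")
        assert t.rooted
        assert sorted(t.leaf_labels()) == ["a", "b", "c"]
        assert len(t.root.children) == 2

    def test_basal_trifurcation_is_unrooted(self):
        t = parse_newick("(a,b,c);")
        assert not t.rooted
        assert len(t.root.children) == 3

    def test_round_trip_preserves_lengths(self):
        text = "((a:0.1234567891,b:1):0.5,(c:2,d:1e-06):1);"
        t = parse_newick(text)
        t2 = parse_newick(write_newick(t))
        pairs = zip(t.postorder(), t2.postorder())
        for n1, n2 in pairs:
            assert n1.label == n2.label
            assert n1.length == pytest.approx(n2.length, rel=1e-10)

    def test_unbalanced_parentheses_error_reports_position(self):
        with pytest.raises(TreeError, match="position"):
            parse_newick("((a:1,b:1):1,c:2;")

    def test_mrca(self):
        t = parse_newick("((a:1,b:1)ab:1,(c:1,d:1)cd:1)r;")
        assert t.mrca({"a", "b"}).label == "ab"
        assert t.mrca({"a", "c"}).label == "r"


class TestIdentityCoverage:
    def test_identical_sequences(self):
        s = Sequence("x", "MKVLAAGGYT", "aa")
        ident, cov = pairwise_identity_coverage(s, s)
        assert ident == 1.0 and cov == 1.0

    def test_query_is_first_half_of_reference(self):
        ref = Sequence("ref", "MKVLAAGGYTWERTPLSNDH", "aa")
        qry = Sequence("q", "MKVLAAGGYT", "aa")
        ident, cov = pairwise_identity_coverage(qry, ref)
        assert ident == 1.0
        assert cov == pytest.approx(0.5)

    def test_single_mismatch_no_gaps(self):
        # hand alignment: MKV vs MRV, one substitution in three columns
        ident, cov = pairwise_identity_coverage(
            Sequence("a", "MKV", "aa"), Sequence("b", "MRV", "aa")
        )
        assert ident == pytest.approx(2 / 3)
        assert cov == 1.0

    def test_identity_is_symmetric(self):
        a = Sequence("a", "MKVLAAGGYTWERT", "aa")
        b = Sequence("b", "MKVAAGGYSWERT", "aa")
        ia, _ = pairwise_identity_coverage(a, b)
        ib, _ = pairwise_identity_coverage(b, a)
        assert ia == pytest.approx(ib)

    def test_ambiguity_never_matches(self):
        ident, _ = pairwise_identity_coverage(
            Sequence("a", "MXV", "aa"), Sequence("b", "MXV", "aa")
        )
        assert ident == pytest.approx(2 / 3)

    def test_empty_sequence_rejected(self):
        with pytest.raises(SequenceError):
            pairwise_identity_coverage(
                Sequence("a", "---", "aa"), Sequence("b", "MKV", "aa")
            )


class TestFilterInputs:
    def _family(self):
        ref = Sequence("ref", "MKVLAAGGYTWERTPLSNDHKRVQAEFGHLM" * 3, "aa")
        return ref

    def test_reference_itself_is_ingroup(self):
        ref = self._family()
        ingroup, outgroup, _ = filter_inputs([ref], ref)
        assert [s.identifier for s in ingroup] == ["ref"]
        assert outgroup == []

    def test_mid_identity_lands_in_outgroup(self):
        # identity between 0.50 and 0.60: passes inclusion, then outgroup rule
        ref = Sequence("ref", "MKVLAAGGYTWERTPLSNDH" * 4, "aa")
        res = list(ref.residues)
        rng = np.random.default_rng(1)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for i in range(0, len(res), 9):  # mutate ~44% of positions
            for j in (i, i + 1, i + 2, i + 3):
                if j < len(res):
                    res[j] = aas[rng.integers(20)]
        cand = Sequence("mid", "".join(res), "aa")
        ident, cov = pairwise_identity_coverage(cand, ref)
        assert 0.50 <= ident < 0.60 and cov >= 0.9  # fixture sanity
        ingroup, outgroup, _ = filter_inputs([cand, ref], ref)
        assert [s.identifier for s in outgroup] == ["mid"]
        assert [s.identifier for s in ingroup] == ["ref"]

    def test_low_coverage_discarded(self):
        ref = self._family()
        frag = Sequence("frag", ref.residues[: len(ref.residues) // 2], "aa")
        ingroup, outgroup, report = filter_inputs([frag, ref], ref)
        decisions = {r[0]: r[3] for r in report}
        assert decisions["frag"] == "discarded"
        assert "frag" not in [s.identifier for s in ingroup + outgroup]

    def test_empty_ingroup_is_error(self):
        ref = self._family()
        frag = Sequence("frag", ref.residues[:20], "aa")
        with pytest.raises(SequenceError, match="ingroup"):
            filter_inputs([frag], ref)


class TestRooting:
    def test_single_taxon_outgroup(self):
        t = parse_newick("((a:1,b:1):1,(c:1,o:2):1);")
        rooted = root_by_outgroup(t, {"o"})
        assert rooted.rooted
        # root separates o from the rest
        below = {}
        for n in rooted.postorder():
            below[id(n)] = {n.label} if n.is_leaf else set().union(
                *(below[id(c)] for c in n.children)
            )
        kids = [below[id(c)] for c in rooted.root.children]
        assert {"o"} in kids

    def test_total_length_conserved(self):
        t = parse_newick("((a:1,b:1):1,(c:1,o:2):0.5);")
        before = t.total_branch_length()
        rooted = root_by_outgroup(t, {"o"})
        assert rooted.total_branch_length() == pytest.approx(before, rel=1e-9)

    def test_attachment_branch_split_in_half(self):
        t = parse_newick("((a:1,b:1):1,(c:1,o:2):0.5);")
        rooted = root_by_outgroup(t, {"o"})
        lengths = sorted(c.length for c in rooted.root.children)
        assert lengths == [1.0, 1.0]  # o's branch of 2 split 50:50

    def test_non_monophyletic_outgroup_rejected(self):
        t = parse_newick("((a:1,b:1):1,(c:1,o:2):1);")
        with pytest.raises(TreeError, match="monophyletic"):
            root_by_outgroup(t, {"a", "c"})

    def test_bipartitions_invariant_under_rooting(self):
        t = parse_newick("(((a:1,b:1):1,(c:1,d:1):2):1,(e:1,o:2):1);")
        before = t.bipartitions()
        after = root_by_outgroup(t, {"o"}).bipartitions()
        assert before == after
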