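"""Sequence, alignment and tree containers plus standard-format I/O.

The core data types used throughout the pipeline live here: :class:`Sequence`
(a named residue string over a declared alphabet), :class:`Alignment` (a
rectangular character matrix) and :class:`PhyloTree` (a rooted or unrooted
phylogeny with branch lengths in expected substitutions per site and optional
node ages in Myr).  FASTA parsing goes through Biopython, Newick parsing
through dendropy; both are re-exposed behind small wrappers so the rest of
the package never touches a third-party record type.

Also here: the identity/coverage input filter used to assemble the ingroup
and outgroup for a reconstruction, and outgroup rooting.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

import dendropy
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

AA_ALPHABET = "aa"
NT_ALPHABET = "nt"
CODON_ALPHABET = "codon"

AA_CHARS = set("ACDEFGHIKLMNPQRSTVWY") | {"X", "-"}
NT_CHARS = set("ACGT") | {"N", "-"}
GAP = "-"


class SequenceError(ValueError):
    pass


class TreeError(ValueError):
    pass


@dataclass
class Sequence:
    """A named residue string over a declared alphabet.

    Codon sequences are stored as nucleotide strings whose length is a
    multiple of three; one codon-alignment "column" is a triplet.
    """

    identifier: str
    residues: str
    alphabet: str = AA_ALPHABET

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        allowed = AA_CHARS if self.alphabet == AA_ALPHABET else NT_CHARS
        bad = set(self.residues) - allowed
        if bad:
            raise SequenceError(
                f"sequence {self.identifier!r}: characters {sorted(bad)} not in "
                f"{self.alphabet!r} alphabet"
            )
        if self.alphabet == CODON_ALPHABET and len(self.residues) % 3 != 0:
            raise SequenceError(
                f"sequence {self.identifier!r}: codon sequence length "
                f"{len(self.residues)} is not a multiple of 3"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def n_columns(self) -> int:
        """Alignment columns: residues for aa/nt, triplets for codon."""
        if self.alphabet == CODON_ALPHABET:
            return len(self.residues) // 3
        return len(self.residues)

    def column(self, i: int) -> str:
        """1-based column access (a triplet for codon sequences)."""
        j = i - 1
        if self.alphabet == CODON_ALPHABET:
            return self.residues[3 * j : 3 * j + 3]
        return self.residues[j]

    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")


@dataclass
class Alignment:
    """Rectangular alignment; columns are 1-based throughout the package."""

    sequences: list[Sequence]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise SequenceError("alignment has no sequences")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise SequenceError(f"ragged alignment: row lengths {sorted(lengths)}")
        alphabets = {s.alphabet for s in self.sequences}
        if len(alphabets) != 1:
            raise SequenceError(f"mixed alphabets in alignment: {sorted(alphabets)}")
        ids = [s.identifier for s in self.sequences]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise SequenceError(f"duplicate identifiers in alignment: {dup}")

    @property
    def alphabet(self) -> str:
        return self.sequences[0].alphabet

    @property
    def n_taxa(self) -> int:
        return len(self.sequences)

    @property
    def n_columns(self) -> int:
        return self.sequences[0].n_columns

    @property
    def identifiers(self) -> list[str]:
        return [s.identifier for s in self.sequences]

    def column(self, i: int) -> list[str]:
        return [s.column(i) for s in self.sequences]

    def take_columns(self, columns: list[int]) -> "Alignment":
        """New alignment made of the given 1-based columns, in the given order."""
        for c in columns:
            if not 1 <= c <= self.n_columns:
                raise SequenceError(f"column {c} out of range 1..{self.n_columns}")
        out = []
        for s in self.sequences:
            out.append(
                Sequence(s.identifier, "".join(s.column(c) for c in columns), s.alphabet)
            )
        return Alignment(out)

    def drop_all_gap_columns(self) -> "Alignment":
        keep = [
            c
            for c in range(1, self.n_columns + 1)
            if any(set(x) != {GAP} for x in self.column(c))
        ]
        return self.take_columns(keep)

    def get(self, identifier: str) -> Sequence:
        for s in self.sequences:
            if s.identifier == identifier:
                return s
        raise SequenceError(f"identifier {identifier!r} not in alignment")

    def subset(self, identifiers: list[str]) -> "Alignment":
        return Alignment([self.get(i) for i in identifiers])


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path, alphabet: str = AA_ALPHABET) -> list[Sequence]:
    """Read a FASTA file; identifiers are the header token up to whitespace."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"no FASTA records in {path}")
    seen: set[str] = set()
    out: list[Sequence] = []
    for rec in records:
        if rec.id in seen:
            raise SequenceError(f"duplicate identifier {rec.id!r} in {path}")
        seen.add(rec.id)
        out.append(Sequence(rec.id, str(rec.seq), alphabet))
    return out


def write_fasta(sequences: list[Sequence], path) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.identifier, description="") for s in sequences
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def fasta_string(sequences: list[Sequence]) -> str:
    records = [
        SeqRecord(Seq(s.residues), id=s.identifier, description="") for s in sequences
    ]
    buf = io.StringIO()
    SeqIO.write(records, buf, "fasta")
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Trees


class Node:
    """Tree node; ``length`` is the branch to the parent (subs/site)."""

    __slots__ = ("label", "length", "parent", "children", "age")

    def __init__(self, label: str | None = None, length: float = 0.0):
        self.label = label
        self.length = float(length)
        self.parent: Node | None = None
        self.children: list[Node] = []
        self.age: float | None = None

    def add_child(self, node: "Node") -> "Node":
        node.parent = self
        self.children.append(node)
        return node

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover
        return f"Node({self.label!r}, len={self.length:g})"


class PhyloTree:
    """Rooted tree container (an unrooted tree is held with a basal
    multifurcation and ``rooted=False``)."""

    def __init__(self, root: Node, rooted: bool = True):
        self.root = root
        self.rooted = rooted

    # -- traversal ---------------------------------------------------------
    def postorder(self) -> list[Node]:
        out: list[Node] = []

        def rec(n: Node) -> None:
            for c in n.children:
                rec(c)
            out.append(n)

        rec(self.root)
        return out

    def preorder(self) -> list[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(reversed(n.children))
        return out

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def internal_nodes(self, include_root: bool = True) -> list[Node]:
        out = [n for n in self.postorder() if not n.is_leaf]
        if not include_root:
            out = [n for n in out if n is not self.root]
        return out

    def total_branch_length(self) -> float:
        return sum(n.length for n in self.postorder() if n.parent is not None)

    def copy(self) -> "PhyloTree":
        def rec(n: Node) -> Node:
            m = Node(n.label, n.length)
            m.age = n.age
            for c in n.children:
                m.add_child(rec(c))
            return m

        return PhyloTree(rec(self.root), rooted=self.rooted)

    # -- queries -----------------------------------------------------------
    def find_leaf(self, label: str) -> Node:
        for n in self.leaves():
            if n.label == label:
                return n
        raise TreeError(f"leaf {label!r} not in tree")

    def mrca(self, labels) -> Node:
        labels = set(labels)
        known = set(self.leaf_labels())
        unknown = labels - known
        if unknown:
            raise TreeError(f"taxa not in tree: {sorted(unknown)}")
        below: dict[Node, set[str]] = {}
        for n in self.postorder():
            if n.is_leaf:
                below[n] = {n.label}
            else:
                below[n] = set().union(*(below[c] for c in n.children))
        for n in self.postorder():
            if labels <= below[n]:
                return n
        return self.root

    def bipartitions(self) -> set[frozenset[str]]:
        """Leaf-label bipartitions induced by internal edges, each encoded as
        the side not containing a fixed reference leaf (rooting-invariant)."""
        all_leaves = set(self.leaf_labels())
        ref = min(all_leaves)
        out: set[frozenset[str]] = set()
        below: dict[Node, set[str]] = {}
        for n in self.postorder():
            below[n] = (
                {n.label} if n.is_leaf else set().union(*(below[c] for c in n.children))
            )
        for n in self.postorder():
            if n.parent is None or n.is_leaf:
                continue
            side = below[n] if ref not in below[n] else all_leaves - below[n]
            # trivial splits (one leaf vs rest) carry no information
            if 1 < len(side) < len(all_leaves) - 1:
                out.add(frozenset(side))
        return out

    # -- ages --------------------------------------------------------------
    def set_ages_from_branch_durations(self) -> None:
        """Interpret branch lengths as durations and set node ages (leaves 0)."""
        depth: dict[Node, float] = {self.root: 0.0}
        for n in self.preorder():
            if n.parent is not None:
                depth[n] = depth[n.parent] + n.length
        height = max(depth[leaf] for leaf in self.leaves())
        for n in self.postorder():
            n.age = height - depth[n]

    def check_age_invariants(self, tol: float = 1e-9) -> None:
        for n in self.postorder():
            if n.age is None:
                raise TreeError(f"node {n.label!r} has no age")
            if n.parent is not None and n.parent.age is not None:
                if n.parent.age < n.age - tol:
                    raise TreeError(
                        f"age inversion: parent {n.parent.age} < child {n.age}"
                    )


# -- Newick -----------------------------------------------------------------


def _from_dendropy(dtree: dendropy.Tree) -> PhyloTree:
    def rec(dn) -> Node:
        label = dn.taxon.label if dn.taxon is not None else dn.label
        length = dn.edge.length if dn.edge.length is not None else 0.0
        n = Node(label, length)
        for dc in dn.child_nodes():
            n.add_child(rec(dc))
        return n

    root = rec(dtree.seed_node)
    rooted = len(root.children) == 2
    return PhyloTree(root, rooted=rooted)


def read_newick(path) -> PhyloTree:
    with open(path) as fh:
        return parse_newick(fh.read())


def parse_newick(text: str) -> PhyloTree:
    if text.count("(") != text.count(")"):
        # report the position after the last unmatched opener for diagnostics
        depth, pos = 0, 0
        for i, ch in enumerate(text):
            if ch == "(":
                depth += 1
                pos = i
            elif ch == ")":
                depth -= 1
        raise TreeError(f"unbalanced parentheses in Newick (near position {pos})")
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"Newick parse error: {exc}") from exc
    return _from_dendropy(dtree)


def write_newick(tree: PhyloTree, path=None) -> str:
    def fmt(x: float) -> str:
        return f"{x:.10g}"

    def rec(n: Node) -> str:
        if n.is_leaf:
            return f"{n.label}:{fmt(n.length)}"
        inner = ",".join(rec(c) for c in n.children)
        label = n.label or ""
        if n.parent is None:
            return f"({inner}){label}"
        return f"({inner}){label}:{fmt(n.length)}"

    text = rec(tree.root) + ";\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def write_age_table(tree: PhyloTree, path=None) -> str:
    """Node ages as a tab-separated sidecar (node_label, age_Myr).

    Internal nodes without labels are assigned stable preorder labels nd1..ndK
    (also set on the tree in place so Newick output matches the table).
    """
    k = 0
    rows = []
    for n in tree.preorder():
        if not n.is_leaf and not n.label:
            k += 1
            n.label = f"nd{k}"
        age = n.age if n.age is not None else float("nan")
        rows.append(f"{n.label}\t{age:.6f}")
    text = "node_label\tage_Myr\n" + "\n".join(rows) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------------------
# Pairwise identity / coverage filter

_ALIGNER = None


def _aligner() -> PairwiseAligner:
    global _ALIGNER
    if _ALIGNER is None:
        a = PairwiseAligner()
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -10.0
        a.extend_gap_score = -1.0
        a.mode = "global"
        _ALIGNER = a
    return _ALIGNER


def pairwise_identity_coverage(query: Sequence, reference: Sequence):
    """Global-alignment identity and reference coverage of a sequence pair.

    Identity is identical residue pairs over aligned columns excluding
    terminal gap overhangs (internal gap columns count in the denominator;
    ambiguity characters never count as matches).  Coverage is the fraction
    of reference residues inside the non-terminal-gap region.
    """
    if query.alphabet != AA_ALPHABET or reference.alphabet != AA_ALPHABET:
        raise SequenceError("identity/coverage filter requires amino-acid sequences")
    q = query.ungapped()
    r = reference.ungapped()
    if not q or not r:
        raise SequenceError("empty sequence in pairwise comparison")
    aln = _aligner().align(q, r)[0]
    rows = str(aln).strip().split("\n")
    # Biopython's alignment text has query/consensus/target lines; rebuild
    # gapped strings from the coordinate arrays instead (robust to wrapping).
    qa, ra = _gapped_pair(q, r, aln.aligned)
    n = len(qa)
    # terminal gap region: leading/trailing columns where either row is gap
    start = 0
    while start < n and (qa[start] == GAP or ra[start] == GAP):
        start += 1
    end = n
    while end > 0 and (qa[end - 1] == GAP or ra[end - 1] == GAP):
        end -= 1
    if end <= start:  # alignment is all overhang (no aligned core)
        return 0.0, 0.0
    matches = 0
    core = 0
    ref_core = 0
    for i in range(start, end):
        core += 1
        if ra[i] != GAP:
            ref_core += 1
        if qa[i] == ra[i] and qa[i] not in ("X", GAP):
            matches += 1
    identity = matches / core
    coverage = ref_core / len(r)
    return identity, coverage


def _gapped_pair(q: str, r: str, aligned) -> tuple[str, str]:
    """Rebuild gapped strings from PairwiseAligner aligned blocks."""
    qa, ra = [], []
    qpos, rpos = 0, 0
    qblocks, rblocks = aligned
    for (qs, qe), (rs, re) in zip(qblocks, rblocks):
        if qs > qpos:
            qa.append(q[qpos:qs])
            ra.append(GAP * (qs - qpos))
        if rs > rpos:
            qa.append(GAP * (rs - rpos))
            ra.append(r[rpos:rs])
        qa.append(q[qs:qe])
        ra.append(r[rs:re])
        qpos, rpos = qe, re
    if qpos < len(q):
        qa.append(q[qpos:])
        ra.append(GAP * (len(q) - qpos))
    if rpos < len(r):
        qa.append(GAP * (len(r) - rpos))
        ra.append(r[rpos:])
    return "".join(qa), "".join(ra)


def filter_inputs(
    candidates: list[Sequence],
    reference: Sequence,
    min_identity: float = 0.50,
    min_coverage: float = 0.90,
    outgroup_identity: float = 0.60,
):
    """Partition candidates into ingroup / outgroup against a reference.

    A candidate is included if identity >= ``min_identity`` and coverage >=
    ``min_coverage``; included candidates with identity below
    ``outgroup_identity`` are designated outgroup.  Everything else is
    discarded with a logged reason.
    """
    for thr in (min_identity, min_coverage):
        if not 0 < thr < 1:
            raise ValueError("thresholds must lie in (0,1)")
    ingroup: list[Sequence] = []
    outgroup: list[Sequence] = []
    report: list[tuple[str, float, float, str]] = []
    for cand in candidates:
        ident, cov = pairwise_identity_coverage(cand, reference)
        if ident < min_identity or cov < min_coverage:
            reason = "discarded"
            logger.info(
                "filter: %s discarded (identity %.3f, coverage %.3f)",
                cand.identifier, ident, cov,
            )
        elif ident < outgroup_identity:
            reason = "outgroup"
            outgroup.append(cand)
        else:
            reason = "ingroup"
            ingroup.append(cand)
        report.append((cand.identifier, ident, cov, reason))
    if not ingroup:
        raise SequenceError("input filter left an empty ingroup")
    return ingroup, outgroup, report


# ---------------------------------------------------------------------------
# Outgroup rooting


def root_by_outgroup(tree: PhyloTree, outgroup_taxa) -> PhyloTree:
    """Root on the branch separating the outgroup from the ingroup.

    The outgroup must be monophyletic in some rooting of the tree; the root
    is placed at the midpoint of the attachment branch.
    """
    outgroup_taxa = set(outgroup_taxa)
    all_leaves = set(tree.leaf_labels())
    missing = outgroup_taxa - all_leaves
    if missing:
        raise TreeError(f"outgroup taxa not in tree: {sorted(missing)}")
    if not outgroup_taxa or outgroup_taxa == all_leaves:
        raise TreeError("outgroup must be a proper nonempty subset of leaves")

    dtree = dendropy.Tree.get(
        data=write_newick(tree), schema="newick", preserve_underscores=True
    )
    dtree.is_rooted = False
    target = None
    for edge in dtree.preorder_edge_iter():
        if edge.head_node is dtree.seed_node:
            continue
        below = {lf.taxon.label for lf in edge.head_node.leaf_iter()}
        if below == outgroup_taxa or (all_leaves - below) == outgroup_taxa:
            target = edge
            break
    if target is None:
        # find a minimal conflicting bipartition for the error message
        for edge in dtree.preorder_edge_iter():
            if edge.head_node is dtree.seed_node:
                continue
            below = {lf.taxon.label for lf in edge.head_node.leaf_iter()}
            if below & outgroup_taxa and below - outgroup_taxa and len(below) < len(all_leaves):
                raise TreeError(
                    "outgroup is not monophyletic; conflicting bipartition "
                    f"{sorted(below)} | {sorted(all_leaves - below)}"
                )
        raise TreeError("outgroup is not monophyletic in any rooting")
    length = target.length or 0.0
    dtree.reroot_at_edge(target, length1=length / 2.0, length2=length / 2.0)
    out = _from_dendropy(dtree)
    out.rooted = True
    return out
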