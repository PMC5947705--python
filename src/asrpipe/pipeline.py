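"""End-to-end orchestration of the reconstruction workflow.

One config drives the whole chain: input filtering against a reference,
block trimming, model choice, ML tree search with optional bootstrap,
outgroup rooting, calibrated dating, three-track ancestral inference at a
target node, ancestral gap inference, consensus with ambiguity resolution,
and back-translation.  Every stage records its parameters and outputs in a
manifest; a rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import minimize

from . import ancestors as A
from . import consensus as C
from . import models as M
from . import mltree as T
from . import trim as TR
from .dating import Calibration, date_clock, date_nprs, node_age
from .seqio import (
    GAP,
    Alignment,
    PhyloTree,
    Sequence,
    filter_inputs,
    read_fasta,
    root_by_outgroup,
    write_fasta,
    write_newick,
    write_age_table,
)

STAGES = (
    "load", "filter", "trim", "model_select", "tree", "bootstrap", "root",
    "date", "reconstruct", "gaps", "consensus", "backtranslate",
)


class PipelineError(ValueError):
    pass


@dataclass
class PipelineConfig:
    aa_fasta: str = ""
    dna_fasta: str = ""
    reference: str = ""
    min_identity: float = 0.50
    min_coverage: float = 0.90
    outgroup_identity: float = 0.60
    outgroup: tuple = ()               # explicit outgroup taxa (overrides filter)
    trim_min_block_length: int = 10
    trim_max_contiguous_nonconserved: int = 8
    trim_max_gap_fraction: float = 0.0
    model_selection: bool = False
    tree_model: str = "WAG+F+G"
    nt_model: str = "GTR+G"
    bootstrap_replicates: int = 1024
    calibration_taxa: tuple = ()
    calibration_age: float = 3190.0     # Myr
    dating_method: str = "clock"
    target_taxa: tuple = ()             # MRCA of these; default: ingroup
    codon_confidence_threshold: float = 0.5
    overrides_file: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_identity", "min_coverage", "outgroup_identity",
                     "codon_confidence_threshold"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise PipelineError(f"{name}={v} outside [0,1]")
        if self.calibration_age <= 0:
            raise PipelineError("calibration age must be positive")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Flat key = value text config; '#' starts a comment."""
        kwargs = {}
        tuple_keys = {"outgroup", "calibration_taxa", "target_taxa"}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in cls.__dataclass_fields__:
                raise PipelineError(f"unknown config key {key!r}")
            ftype = cls.__dataclass_fields__[key].type
            if key in tuple_keys:
                kwargs[key] = tuple(x.strip() for x in value.split(",") if x.strip())
            elif ftype == "bool":
                kwargs[key] = value.lower() in ("1", "true", "on", "yes")
            elif ftype == "int":
                kwargs[key] = int(value)
            elif ftype == "float":
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


def _check_translation(aa: list[Sequence], dna: list[Sequence]) -> None:
    dna_by_id = {s.identifier: s for s in dna}
    for seq in aa:
        if seq.identifier not in dna_by_id:
            raise PipelineError(f"no coding DNA for {seq.identifier!r}")
        d = dna_by_id[seq.identifier]
        if len(d.residues) != 3 * len(seq.residues):
            raise PipelineError(
                f"{seq.identifier!r}: DNA length {len(d.residues)} is not 3x "
                f"protein length {len(seq.residues)}"
            )
        for i, res in enumerate(seq.residues):
            codon = d.residues[3 * i : 3 * i + 3]
            got = M.translate_codon(codon)
            if res == GAP and codon == "---":
                continue
            if got != res and res != "X" and "N" not in codon:
                raise PipelineError(
                    f"{seq.identifier!r}: codon {codon} at position {i + 1} "
                    f"translates to {got}, protein says {res}"
                )


def _fit_codon_track(tree: PhyloTree, codon_aln: Alignment, seed: int):
    """Fit (kappa, omega, global branch scale) for the codon track on the
    fixed tree topology; returns (scaled tree, model)."""
    pi = M.f3x4_frequencies(codon_aln.sequences)

    def build(theta):
        kappa, omega = np.exp(theta[0]), np.exp(theta[1])
        return M.build_codon(M.CodonModelParams(kappa, omega, pi))

    base_len = {id(n): n.length for n in tree.postorder()}

    def negll(theta):
        model = build(theta[:2])
        scale = np.exp(theta[2])
        work = tree
        for n in work.postorder():
            if n.parent is not None:
                n.length = float(np.clip(base_len[id(n)] * scale, T.BL_MIN, T.BL_MAX))
        try:
            return -T.LikelihoodEngine(work, codon_aln, model).log_likelihood()
        except (M.ModelError, T.LikelihoodError):
            return 1e12

    res = minimize(negll, np.array([np.log(2.0), np.log(0.5), 0.0]),
                   method="Nelder-Mead",
                   options={"xatol": 1e-3, "fatol": 1e-3, "maxiter": 150})
    negll(res.x)  # leave the tree at the fitted scale
    return tree, build(res.x[:2])


def run_asr_pipeline(config: PipelineConfig, outdir) -> Path:
    """Run every stage and write outputs plus a manifest under ``outdir``."""
    out = Path(outdir)
    if out.exists():
        shutil.rmtree(out)
    out.mkdir(parents=True)
    manifest: dict = {"config": asdict(config), "stages": {}}

    def record(stage: str, **info) -> None:
        manifest["stages"][stage] = info

    # ---- load ------------------------------------------------------------
    aa_seqs = read_fasta(config.aa_fasta, "aa")
    dna_seqs = read_fasta(config.dna_fasta, "nt")
    _check_translation(aa_seqs, dna_seqs)
    lengths = {len(s) for s in aa_seqs}
    if len(lengths) != 1:
        raise PipelineError(
            "protein input must be an alignment (equal lengths); got "
            f"{sorted(lengths)}"
        )
    record("load", n_sequences=len(aa_seqs), alignment_columns=lengths.pop())

    # ---- filter ----------------------------------------------------------
    reference = next((s for s in aa_seqs if s.identifier == config.reference), None)
    if reference is None:
        raise PipelineError(f"reference {config.reference!r} not among inputs")
    ingroup, outgroup, freport = filter_inputs(
        aa_seqs, reference, config.min_identity, config.min_coverage,
        config.outgroup_identity,
    )
    if config.outgroup:
        names = set(config.outgroup)
        kept = [s for s in ingroup + outgroup]
        outgroup = [s for s in kept if s.identifier in names]
        ingroup = [s for s in kept if s.identifier not in names]
        missing = names - {s.identifier for s in outgroup}
        if missing:
            raise PipelineError(f"explicit outgroup taxa not retained: {sorted(missing)}")
    with open(out / "filter_report.tsv", "w") as fh:
        fh.write("identifier\tidentity\tcoverage\tdecision\n")
        for ident, idn, cov, why in freport:
            fh.write(f"{ident}\t{idn:.4f}\t{cov:.4f}\t{why}\n")
    kept_ids = [s.identifier for s in aa_seqs
                if s.identifier in {x.identifier for x in ingroup + outgroup}]
    out_ids = sorted(s.identifier for s in outgroup)
    in_ids = [i for i in kept_ids if i not in set(out_ids)]
    if not outgroup:
        raise PipelineError("no outgroup available for rooting")
    aa_aln = Alignment([s for s in aa_seqs if s.identifier in set(kept_ids)])
    nt_aln = Alignment(
        [s for s in dna_seqs if s.identifier in set(kept_ids)]
    )
    codon_aln = Alignment(
        [Sequence(s.identifier, s.residues, "codon") for s in nt_aln.sequences]
    )
    record("filter", ingroup=in_ids, outgroup=out_ids,
           outputs=["filter_report.tsv"])

    # ---- trim ------------------------------------------------------------
    params = TR.TrimParameters(
        max_contiguous_nonconserved=config.trim_max_contiguous_nonconserved,
        min_block_length=config.trim_min_block_length,
        max_gap_fraction=config.trim_max_gap_fraction,
    )
    selection = TR.select_conserved_blocks(aa_aln, params)
    trimmed = TR.apply_blocks(aa_aln, selection)
    if trimmed.n_columns == 0:
        raise PipelineError("trimming left no columns; relax trim parameters")
    (out / "blocks.tsv").write_text(selection.report())
    write_fasta(trimmed.sequences, out / "trimmed.fasta")
    record("trim", kept_columns=selection.kept_columns,
           n_blocks=len(selection.blocks), outputs=["blocks.tsv", "trimmed.fasta"])

    # ---- model selection -------------------------------------------------
    if config.model_selection:
        table = T.select_model_aic(trimmed)
        table.to_csv(out / "model_selection.tsv", sep="\t", index=False)
        tree_model_name = str(table.iloc[0]["model"])
        record("model_select", method="AIC", best=tree_model_name,
               outputs=["model_selection.tsv"])
    else:
        tree_model_name = config.tree_model
        record("model_select", method="configured", best=tree_model_name)

    # ---- tree ------------------------------------------------------------
    spec = T.ModelSpec(tree_model_name)
    base = M.build_empirical_aa(
        "WAG", M.empirical_aa_frequencies(trimmed) if spec.empirical_freqs else None
    )
    d = T.ml_distance_matrix(trimmed, base)
    nj = T.nj_tree(d, trimmed.identifiers)
    ll0, aa_model, aa_rates = T._fit_candidate(spec, trimmed, nj)
    search = T.nni_search(nj, trimmed, aa_model, aa_rates)
    # refit rate parameters on the searched tree, then refresh branch lengths
    _, aa_model, aa_rates = T._fit_candidate(spec, trimmed, search.tree)
    final_tree = T.optimize_branch_lengths(
        search.tree, trimmed, aa_model, aa_rates, tol=1e-4
    )
    search = T.LikelihoodEngine(final_tree, trimmed, aa_model, aa_rates).result()
    write_newick(search.tree, out / "ml_tree.nwk")
    record("tree", model=tree_model_name, log_likelihood=round(search.log_likelihood, 6),
           outputs=["ml_tree.nwk"])

    # ---- bootstrap -------------------------------------------------------
    if config.bootstrap_replicates > 0:
        bs = T.bootstrap_support(
            trimmed, aa_model, aa_rates,
            n_replicates=config.bootstrap_replicates,
            seed=config.seed, best_tree=search.tree,
        )
        write_newick(bs.annotate(), out / "bootstrap_tree.nwk")
        record("bootstrap", n_replicates=config.bootstrap_replicates,
               outputs=["bootstrap_tree.nwk"])
    else:
        record("bootstrap", n_replicates=0, skipped=True)

    # ---- root ------------------------------------------------------------
    rooted = root_by_outgroup(search.tree, out_ids)
    write_newick(rooted, out / "rooted_tree.nwk")
    record("root", outgroup=out_ids, outputs=["rooted_tree.nwk"])

    # ---- date ------------------------------------------------------------
    cal_taxa = tuple(config.calibration_taxa) or tuple(rooted.leaf_labels())
    calibration = Calibration(frozenset(cal_taxa), config.calibration_age)
    if config.dating_method == "clock":
        chron = date_clock(rooted, calibration, n_sites=trimmed.n_columns)
    elif config.dating_method == "nprs":
        # basal branches pooled: the 50:50 root placement on the outgroup
        # attachment branch is arbitrary and must not be penalized
        chron = date_nprs(rooted, calibration, seed=config.seed, root_rates="pooled")
    else:
        raise PipelineError(f"unknown dating method {config.dating_method!r}")
    write_newick(chron.tree, out / "chronogram.nwk")
    write_age_table(chron.tree, out / "node_ages.tsv")
    target_taxa = tuple(config.target_taxa) or tuple(in_ids)
    target_age = node_age(chron, target_taxa)
    record("date", method=config.dating_method, calibration_age=config.calibration_age,
           target_node_age=round(target_age, 4),
           outputs=["chronogram.nwk", "node_ages.tsv"])

    # ---- reconstruct (three tracks) --------------------------------------
    # amino-acid track: branch lengths refreshed on the full alignment
    aa_tree = T.optimize_branch_lengths(rooted, aa_aln, aa_model, aa_rates, tol=1e-3)
    aa_target = aa_tree.mrca(target_taxa)
    aa_post = A.marginal_posteriors(aa_tree, aa_aln, aa_model, aa_rates, aa_target)

    # nucleotide track: GTR(+G) with its own branch lengths
    nt_spec = T.ModelSpec(config.nt_model)
    nt_seed_model = M.build_gtr(np.ones(6), np.full(4, 0.25))
    nt_tree = T.optimize_branch_lengths(rooted, nt_aln, nt_seed_model, tol=1e-2)
    _, nt_model, nt_rates = T._fit_candidate(nt_spec, nt_aln, nt_tree)
    nt_tree = T.optimize_branch_lengths(nt_tree, nt_aln, nt_model, nt_rates, tol=1e-2)
    nt_target = nt_tree.mrca(target_taxa)
    nt_post = A.marginal_posteriors(nt_tree, nt_aln, nt_model, nt_rates, nt_target)

    # codon track: M0 with F3x4 frequencies, kappa/omega and a branch scale
    codon_tree, codon_model = _fit_codon_track(aa_tree.copy(), codon_aln, config.seed)
    codon_target = codon_tree.mrca(target_taxa)
    codon_post = A.marginal_posteriors(codon_tree, codon_aln, codon_model, None,
                                       codon_target)
    for name, post in (("aa", aa_post), ("nt", nt_post), ("codon", codon_post)):
        (out / f"posteriors_{name}.tsv").write_text(post.dump())
    record("reconstruct", target_taxa=list(target_taxa),
           target_node=aa_target.label or "ingroup_mrca",
           outputs=[f"posteriors_{x}.tsv" for x in ("aa", "nt", "codon")])

    # ---- gaps ------------------------------------------------------------
    gap_mask = A.infer_ancestral_gaps(aa_tree, aa_aln, aa_target)
    record("gaps", n_gap_columns=int(gap_mask.sum()))

    # ---- consensus -------------------------------------------------------
    aa_map = A.map_sequence(aa_post, gap_mask)
    nt_gap_mask = np.repeat(gap_mask, 3)
    nt_map = A.map_sequence(nt_post, nt_gap_mask)
    codon_map = A.map_sequence(codon_post, gap_mask)
    aa_track = aa_map.sequence.residues
    nt_translated = M.translate(nt_map.sequence.residues).replace("*", "X")
    codon_translated = M.translate(codon_map.sequence.residues).replace("*", "X")

    result = C.three_way_consensus(aa_track, nt_translated, codon_translated, gap_mask)
    overrides = _read_overrides(config.overrides_file) if config.overrides_file else {}
    result = C.resolve_ambiguities(
        result, codon_translated, codon_post.map_probabilities,
        extant_alignment=aa_aln,
        codon_confidence_threshold=config.codon_confidence_threshold,
        manual_overrides=overrides,
    )
    report, amb_fraction = C.ambiguity_report(result)
    report.to_csv(out / "ambiguity_report.tsv", sep="\t", index=False)
    metrics = A.confidence_metrics(
        {"aa": aa_post, "nt": nt_post, "codon": codon_post}, gap_mask
    )
    consensus_seq = result.sequence("ancestor")
    write_fasta([consensus_seq], out / "ancestor.fasta")
    for name, m in (("aa", aa_map), ("nt", nt_map), ("codon", codon_map)):
        write_fasta([Sequence(f"ancestor_{name}", m.sequence.residues,
                              m.sequence.alphabet)], out / f"ancestor_{name}.fasta")
    record("consensus", ambiguous_fraction=round(amb_fraction, 6),
           outputs=["ancestor.fasta", "ambiguity_report.tsv"])

    # ---- backtranslate ---------------------------------------------------
    keep = [i for i, call in enumerate(result.calls) if call.residue != GAP]
    ungapped = Sequence("ancestor", "".join(result.calls[i].residue for i in keep), "aa")
    codon_track_ungapped = Sequence(
        "codon_track",
        "".join(codon_map.sequence.residues[3 * i : 3 * i + 3] for i in keep),
        "nt",
    )
    dna = C.backtranslate(ungapped, codon_track_ungapped)
    write_fasta([dna], out / "ancestor_dna.fasta")
    record("backtranslate", n_codons=len(dna.residues) // 3,
           outputs=["ancestor_dna.fasta"])

    # ---- metrics + manifest ---------------------------------------------
    lines = [
        f"ambiguous_fraction\t{amb_fraction:.6f}",
        f"confidence_aa\t{metrics.per_track['aa']:.5f}",
        f"confidence_codon\t{metrics.per_track['codon']:.5f}",
        f"confidence_nt\t{metrics.per_track['nt']:.5f}",
        f"overall_average_posterior\t{metrics.overall_average_posterior:.4f}",
        f"target_node_age_Myr\t{target_age:.4f}",
        f"tree_log_likelihood\t{search.log_likelihood:.6f}",
    ]
    (out / "metrics.txt").write_text("\n".join(lines) + "\n")
    manifest["metrics_file"] = "metrics.txt"
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n"
    )
    return out


def _read_overrides(path) -> dict[int, str]:
    """Overrides file: tab-separated (column, residue, rationale)."""
    overrides: dict[int, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("column"):
            continue
        parts = line.split("\t")
        overrides[int(parts[0])] = parts[1].strip()
    return overrides
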