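"""End-to-end validation experiments on synthetic data with known ancestors.

The study conditions are fixed here: 16 taxa (one outgroup), 300 codons,
an M0 codon model (kappa 2, omega 0.3) with 4-category gamma rates (shape 1),
branches averaging 0.1 substitutions per codon site, a sprinkling of
codon-granularity indels, a 1000 Myr ingroup root and a calibration at the
1500 Myr outgroup split.  One seed drives everything.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np

from . import models as M
from . import synth
from .pipeline import PipelineConfig, run_asr_pipeline
from .seqio import read_fasta, write_fasta

KAPPA = 2.0
OMEGA = 0.3
GAMMA_SHAPE = 1.0
MEAN_BRANCH_SUBS = 0.1          # substitutions per codon site per branch
ROOT_AGE_MYR = 1000.0
OUTGROUP_STEM_FACTOR = 1.5
CALIBRATION_AGE_MYR = ROOT_AGE_MYR * OUTGROUP_STEM_FACTOR
INDEL_FRACTION = 0.01           # indel events per substitution


def simulate_study_dataset(seed: int, n_taxa: int = 16, n_codons: int = 300):
    """Simulate the standard validation dataset; returns (sim, aa, nt, anc)."""
    chron = synth.add_outgroup(
        synth.simulate_tree(n_taxa - 1, root_age=ROOT_AGE_MYR, seed=seed),
        stem_factor=OUTGROUP_STEM_FACTOR,
    )
    durations = [
        n.parent.age - n.age for n in chron.tree.postorder() if n.parent is not None
    ]
    clock_rate = MEAN_BRANCH_SUBS / float(np.mean(durations))
    model = M.build_codon(M.CodonModelParams(KAPPA, OMEGA))
    sim = synth.simulate_evolution(
        chron,
        model,
        M.discrete_gamma(GAMMA_SHAPE, 4),
        n_codons=n_codons,
        indel_rate=INDEL_FRACTION,
        seed=seed,
        clock_rate=clock_rate,
    )
    aa, nt, _, anc = synth.make_three_track_dataset(sim)
    return sim, aa, nt, anc


def masked_identity(a: str, b: str) -> float:
    """Identity over columns where either sequence has a residue."""
    scored = [(x, y) for x, y in zip(a, b) if x != "-" or y != "-"]
    return sum(x == y for x, y in scored) / len(scored)


def _read_map_track(path: Path):
    """MAP state and probability per column from a posterior dump."""
    states, probs = {}, {}
    for line in Path(path).read_text().splitlines()[1:]:
        _, col, state, p, is_map = line.split("\t")
        if is_map == "1":
            states[int(col)] = state
            probs[int(col)] = float(p)
    n = max(states)
    return [states[i] for i in range(1, n + 1)], np.array(
        [probs[i] for i in range(1, n + 1)]
    )


def end_to_end_recovery(
    seed: int,
    n_taxa: int = 16,
    n_codons: int = 300,
    bootstrap_replicates: int = 0,
    dating_method: str = "clock",
    outdir=None,
) -> dict:
    """Run the full pipeline on one simulated dataset and score it against
    the recorded truth.

    Returns a dict with the consensus-vs-truth identity at the ingroup root,
    posterior calibration counts for high-confidence sites, the ambiguity
    fraction, per-track confidences, and inferred vs true target-node age.
    """
    sim, aa, nt, anc = simulate_study_dataset(seed, n_taxa, n_codons)
    ingroup = tuple(i for i in aa.identifiers if i != "outgrp")
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        write_fasta(aa.sequences, tmp / "aa.fasta")
        write_fasta(nt.sequences, tmp / "nt.fasta")
        cfg = PipelineConfig(
            aa_fasta=str(tmp / "aa.fasta"),
            dna_fasta=str(tmp / "nt.fasta"),
            reference=ingroup[0],
            outgroup=("outgrp",),
            bootstrap_replicates=bootstrap_replicates,
            calibration_taxa=(ingroup[0], "outgrp"),
            calibration_age=CALIBRATION_AGE_MYR,
            dating_method=dating_method,
            target_taxa=ingroup,
            seed=seed,
        )
        run = run_asr_pipeline(cfg, outdir or tmp / "run")
        consensus = read_fasta(run / "ancestor.fasta", "aa")[0].residues
        map_states, map_probs = _read_map_track(run / "posteriors_aa.tsv")
        metrics = {
            k: float(v)
            for k, v in (
                ln.split("\t") for ln in (run / "metrics.txt").read_text().splitlines()
            )
        }
    true_root = anc["node1"]["aa"].residues  # ingroup root of the simulation
    identity = masked_identity(consensus, true_root)
    confident = [
        (map_states[c] == true_root[c])
        for c in range(len(true_root))
        if true_root[c] != "-" and 0.9 <= map_probs[c] <= 1.0
    ]
    return {
        "identity": identity,
        "n_confident": len(confident),
        "n_confident_correct": int(sum(confident)),
        "ambiguous_fraction": metrics["ambiguous_fraction"],
        "confidence_aa": metrics["confidence_aa"],
        "confidence_nt": metrics["confidence_nt"],
        "confidence_codon": metrics["confidence_codon"],
        "overall_average_posterior": metrics["overall_average_posterior"],
        "target_node_age": metrics["target_node_age_Myr"],
        "true_target_age": ROOT_AGE_MYR,
    }


def nprs_recovery(seed: int, n_taxa: int = 16, sigma: float = 0.2) -> list[float]:
    """Relative age errors of rate-smoothing on one relaxed-clock tree.

    Branch lengths are true durations times a lognormal rate jitter; nodes
    younger than 5% of the root age are excluded (their ages carry no
    absolute-time information at this jitter level).
    """
    from .dating import Calibration, date_nprs

    chron = synth.simulate_tree(n_taxa, root_age=ROOT_AGE_MYR, seed=seed)
    tree = chron.tree.copy()
    rng = np.random.default_rng([seed, 1])
    true = {n.label: n.age for n in tree.postorder()}
    for n in tree.postorder():
        if n.parent is not None:
            n.length = (n.parent.age - n.age) * 3e-4 * rng.lognormal(0.0, sigma)
    cal = Calibration(frozenset(tree.leaf_labels()), ROOT_AGE_MYR)
    ch = date_nprs(tree, cal, seed=seed)
    return [
        abs(n.age - true[n.label]) / true[n.label]
        for n in ch.tree.internal_nodes(include_root=False)
        if true[n.label] > 0.05 * ROOT_AGE_MYR
    ]
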