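"""Run the complete workflow on simulated data and score the result.

Simulates a 16-taxon codon dataset with known ancestors, runs filtering,
trimming, tree search, rooting, dating, three-track reconstruction and
consensus, then compares the consensus ancestor with the simulated truth.
"""

from pathlib import Path

from asrpipe.seqio import read_fasta, write_fasta
from asrpipe.pipeline import PipelineConfig, run_asr_pipeline
from asrpipe.validation import (
    CALIBRATION_AGE_MYR,
    masked_identity,
    simulate_study_dataset,
)

workdir = Path("example_run")
workdir.mkdir(exist_ok=True)
sim, aa, nt, ancestors = simulate_study_dataset(seed=11)
write_fasta(aa.sequences, workdir / "aa.fasta")
write_fasta(nt.sequences, workdir / "nt.fasta")
ingroup = tuple(i for i in aa.identifiers if i != "outgrp")

config = PipelineConfig(
    aa_fasta=str(workdir / "aa.fasta"),
    dna_fasta=str(workdir / "nt.fasta"),
    reference=ingroup[0],
    outgroup=("outgrp",),
    bootstrap_replicates=10,
    calibration_taxa=(ingroup[0], "outgrp"),
    calibration_age=CALIBRATION_AGE_MYR,
    target_taxa=ingroup,
    seed=11,
)
run = run_asr_pipeline(config, workdir / "run")
print((run / "metrics.txt").read_text())

consensus = read_fasta(run / "ancestor.fasta", "aa")[0].residues
truth = ancestors["node1"]["aa"].residues  # the simulated ingroup root
print(f"consensus vs true ancestor identity: "
      f"{100 * masked_identity(consensus, truth):.2f}%")
# The metrics file reports the ambiguity rate, per-track confidences and the
# inferred age of the target node (simulated at 1000 Myr, calibrated via the
# 1500 Myr outgroup split); the identity line shows how much of the true
# ancestor the consensus recovered.
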