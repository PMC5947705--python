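# Methods

## Models

All substitution models are continuous-time reversible Markov chains built
as `q_ij = s_ij π_j` from symmetric exchangeabilities `s` and stationary
frequencies `π`, scaled so the mean rate `-Σ_i π_i q_ii` is exactly 1.
Branch lengths therefore mean expected substitutions per site on every
alphabet (per codon site for the 61-state codon model). Transition matrices
come from the symmetrized eigendecomposition `Π^{1/2} Q Π^{-1/2}`, exact for
reversible chains and reused across branch lengths and rate categories; the
test suite cross-checks it against scaling-and-squaring `expm`.

- **Amino acids**: WAG, optionally with empirical frequencies ("+F",
  counted with a 0.1 pseudocount per state). The published exchangeability
  and frequency values ship as a plain-text data file.
- **Nucleotides**: GTR with six exchangeabilities (order AC, AG, AT, CG,
  CT, GT).
- **Codons**: M0-style model on the 61 sense codons; single-nucleotide
  steps only, transition bias κ, nonsynonymous factor ω, frequencies
  uniform, empirical, or F3×4 (per-position nucleotide frequencies
  renormalized over sense codons). Stop codons are excluded from the state
  space by construction.
- **Among-site rate variation**: k equal-weight discrete-gamma categories
  (default k=4) with mean-of-slice category rates — `r_i = k(F_{α+1}(b_{i+1})
  − F_{α+1}(b_i))` for slice boundaries at the quantiles of Gamma(α, α) —
  renormalized to mean exactly 1. An invariant class (+I) with probability
  `p` prepends rate 0 and rescales the gamma rates by `1/(1−p)`.

Gap, `X` and `N` characters are missing data: their conditional-likelihood
vectors are all ones. Stop or partially gapped codons in a codon-track
column are likewise treated as missing.

## Likelihood machinery

`LikelihoodEngine` implements Felsenstein pruning with per-node, per-pattern
scaling factors accumulated in log space, site-pattern compression, and
batched rate categories (arrays shaped `(categories, states, patterns)`).
Besides the inside ("up") pass it maintains an outside pass, so that
`out[v]·up[v]` summed over states gives the pattern likelihood from any node.
This one structure serves three consumers:

- total and per-site log-likelihoods;
- single-branch profiles `f(t)` for coordinate-wise branch-length
  optimization (bounded scalar search per branch, lengths clamped to
  [1e-8, 20], sweeps until the log-likelihood improves by < `tol`,
  default 1e-6; the log-likelihood never decreases at an accepted step);
- marginal ancestral posteriors (below).

Tree search: pairwise ML distances (1-D optimization per pair, capped at
20 substitutions/site) feed neighbor joining (negative estimates clamped to
0), then NNI hill-climbing. Candidate rearrangements are scored with one
optimization sweep over the five branches incident to the rearranged edge;
the best strict improvement (> 1e-9, ties keep the current topology) is
applied and all branch lengths re-optimized. Unrooted trees carry a basal
trifurcation; because every model is reversible the likelihood is invariant
to the virtual root, which the suite verifies. Bootstrap resamples columns
with replacement and reruns the full search per replicate; AIC model choice
(`2k − 2lnL` on a fixed NJ tree) counts substitution, frequency and
rate-variation parameters (e.g. GTR+I+G: 5+3+1+1 = 10).

## Dating

One calibration fixes the age of a named MRCA. Node ages are parameterized
without explicit constraints: nodes on the calibration-to-root path carry
positive increments, every other internal node a logistic fraction of its
parent's age, so parent ≥ child ≥ 0 holds identically and leaves sit at 0.

- **Strict clock** (default): ages and one global rate maximize a Poisson
  likelihood of per-branch substitution counts (branch length × n_sites)
  with mean rate × duration × n_sites. On clocklike input the
  mean-path-depth initialization is already the optimum, giving exact
  recovery of constructed ages.
- **Rate smoothing**: ages minimize Σ over non-root internal nodes, over
  their children, of |rate(parent branch) − rate(child branch)|^p
  (default p=2), with the root contributing each basal branch's deviation
  from the mean basal rate. Five Nelder-Mead starts (the clocklike
  initialization plus four jittered ones, seeded); the best objective wins,
  so the result is never worse than the clock-style start.

Because the position of the root along the branch joining its two children
is unidentifiable under a reversible model, the two basal branches enter the
clock likelihood as one pooled observation (summed length and duration).
Without this, the 50:50 midpoint placement used when rooting on the outgroup
branch biased simulated ingroup-root ages by >15%. For the same reason the
pipeline runs rate smoothing with `root_rates="pooled"` on midpoint-rooted
trees, while the default "mean" form applies when basal lengths are real.

## Ancestral inference and consensus

Marginal posteriors at an internal node v mix rate categories by their
per-site posterior weights; since `P(x|data) = Σ_c w_c P(data, x|c) / Σ_c
w_c P(data|c)`, this equals normalizing the prior-weighted joint, which is
how it is computed. The MAP state per column is the point estimate; exact
ties break by state order (alphabetical) with a logged warning. Ancestral
gap states come from Fitch parsimony on presence/absence with ties resolved
to "present", so residues survive for downstream resolution.

The consensus stage compares the translated amino-acid, nucleotide and
codon tracks per column (synonymous disagreements do not flag). Flagged
columns resolve in a fixed order: manual override (the place where
physicochemical or structural judgment enters, as a recorded input file),
else the codon-track residue when its MAP posterior ≥ 0.5 (the codon track
being the best-informed of the three), else the most frequent extant
residue with ties to the codon track. Resolution is idempotent and flags
are retained for reporting; `ambiguous_fraction` = flagged / non-gap
columns. Back-translation keeps codon-track codons that translate
correctly and otherwise takes the usage-table or first canonical codon, so
the DNA always translates back to the ancestor exactly.

## Synthetic data

The generator emulates the study conditions end to end: a birth–death
time-tree conditioned on the number of extant tips (pure-birth by default),
rescaled to a root age in Myr, optionally extended by a single outgroup
diverging at 1.5× the ingroup root age; codon sequences evolved by the
Gillespie algorithm per site (so an event log exists), with per-site gamma
rate categories and indels at codon granularity (rate per codon site per
unit branch length, geometric lengths with mean 2 codons, applied at the
start of each branch — insertions draw stationary codons, which is
equivalent to letting them evolve for the remainder of the branch).
Per-branch random streams derive from the global seed and a deterministic
preorder branch index, so results do not depend on traversal order.

Keeping indels at whole-codon granularity makes the amino-acid, nucleotide
and codon views exactly column-compatible — the property the three-track
consensus needs — at the cost of realism: real indels are not
codon-aligned, there is no selection against frameshifts to model, and no
alignment error exists in the generated data. Passing tests therefore
demonstrate correctness of the inference machinery given a correct
alignment, not robustness to alignment error.

Standard validation conditions (`asrpipe.validation`): 16 taxa including
the outgroup, 300 codons, κ=2, ω=0.3, gamma shape 1 with 4 categories,
branches averaging 0.1 substitutions per codon site, indels at 1% of the
substitution rate, ingroup root 1000 Myr, calibration 1500 Myr. These sizes
keep a full 10-seed validation sweep to a few minutes on one CPU.

## Numerical choices

- Underflow: per-node scaling with log accumulators; likelihoods floored at
  1e-300 before logs.
- Transition-matrix entries clamped to ≥ 0 (eigendecomposition round-off).
- Branch-length optimizer: bounded Brent, `xatol` 1e-8.
- Degenerate durations in dating floored at 1e-12 Myr.
- Ties — NNI (≤1e-9 log-likelihood): keep current topology; MAP state:
  first state alphabetically, warned; trimming's "most frequent residue":
  alphabetical (affects bookkeeping only); extant-majority: codon-track
  residue.
- All-gap columns are permitted on input; a zero-column trim result is a
  warning-level outcome, not an error.

## Known limitations

- **Deep ages compress under amino-acid branch lengths.** On
  codon-simulated data at the standard conditions, dating the WAG tree
  places the 1000 Myr ingroup root near 850 Myr (~15% young), while dating
  with the true codon model recovers it to ~1%. The distortion is
  model-projection error (codon process seen through an amino-acid model),
  not an optimizer artifact — the clock recovers constructed ages exactly —
  and the same caveat applies to any amino-acid-level dating of real data.
- **Rate smoothing tracks the per-branch jitter floor.** With lognormal
  rate noise σ=0.2 on 16-taxon trees, the smoothing optimum itself sits at
  ~16% mean per-node relative age error (nodes younger than 5% of the root
  age excluded as carrying no timescale); a penalized-likelihood reference
  implementation does considerably worse on identical inputs. Per-node
  relative error at this design is dominated by estimator variance, not
  bias.
- The NNI-from-NJ search is a desk-scale strategy; it has no escape from
  local optima beyond the starting tree, and saturated data (pairwise
  distances near the cap) can genuinely favour pathological topologies.
- The identity/coverage filter uses one deterministic global alignment per
  pair (BLOSUM62, gap open 10 / extend 1), which is coarse by design —
  it only gates inputs, it does not build the analysis alignment (the
  pipeline consumes an existing alignment; alignment construction is out of
  scope).
- The κ/ω codon model is the standard single-step parameterization; no
  full 61-state exchangeability fitting is attempted.
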