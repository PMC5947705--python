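"""Time-reversible substitution models on amino-acid, nucleotide and codon
state spaces, with discrete-gamma (+I) among-site rate variation.

All rate matrices are built as ``q_ij = s_ij * pi_j`` from a symmetric
exchangeability matrix ``s`` and stationary frequencies ``pi``, then scaled to
a mean rate of one substitution per site per unit branch length, so branch
lengths mean the same thing on all three alphabets.  Transition probabilities
come from the symmetrized eigendecomposition of Q, which is exact for
reversible models and lets a single decomposition serve every branch length
and rate category.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

# State orders are alphabetical everywhere; WAG's published (PAML) order is
# permuted on load.
AA_STATES = tuple("ACDEFGHIKLMNPQRSTVWY")
NT_STATES = tuple("ACGT")
_PAML_AA_ORDER = tuple("ARNDCQEGHILKMFPSTWYV")

STOP_CODONS = ("TAA", "TAG", "TGA")
CODON_STATES = tuple(
    c for c in ("".join(p) for p in itertools.product("ACGT", repeat=3))
    if c not in STOP_CODONS
)

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D",
    "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R",
    "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R",
    "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G",
    "GGG": "G",
}

TRANSITIONS = {frozenset("AG"), frozenset("CT")}


def translate_codon(codon: str) -> str:
    """Standard-code translation; gap codon '---' maps to '-', others with
    gaps or ambiguity to 'X'."""
    if codon == "---":
        return "-"
    if codon in STOP_CODONS:
        return "*"
    return _CODON_TABLE.get(codon, "X")


def translate(nt_seq: str) -> str:
    return "".join(
        translate_codon(nt_seq[i : i + 3]) for i in range(0, len(nt_seq), 3)
    )


class ModelError(ValueError):
    pass


@dataclass
class RateMatrix:
    """Normalized time-reversible rate matrix over an ordered state space."""

    states: tuple
    exchangeabilities: np.ndarray
    frequencies: np.ndarray
    Q: np.ndarray = field(init=False)
    name: str = "custom"

    def __post_init__(self) -> None:
        s = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.frequencies, dtype=float)
        n = len(self.states)
        if s.shape != (n, n):
            raise ModelError(f"exchangeability matrix must be {n}x{n}")
        if not np.allclose(s, s.T):
            raise ModelError("exchangeability matrix must be symmetric")
        if np.any(s < 0):
            raise ModelError("exchangeabilities must be nonnegative")
        if abs(pi.sum() - 1.0) > 1e-9:
            raise ModelError(f"frequencies sum to {pi.sum():.12f}, not 1")
        if np.any(pi < 0):
            raise ModelError("frequencies must be nonnegative")
        Q = s * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mean_rate = -float(pi @ np.diag(Q))
        if mean_rate <= 0:
            raise ModelError("degenerate rate matrix (zero mean rate)")
        self.Q = Q / mean_rate
        self.frequencies = pi
        self.exchangeabilities = s / mean_rate
        self._decompose()

    def _decompose(self) -> None:
        # pi^(1/2) Q pi^(-1/2) is symmetric for reversible Q
        pi = self.frequencies
        mask = pi > 0
        sqrt_pi = np.sqrt(np.where(mask, pi, 1.0))
        B = (sqrt_pi[:, None] * self.Q) / sqrt_pi[None, :]
        w, U = np.linalg.eigh((B + B.T) / 2.0)
        self._eigval = w
        self._left = U.T * sqrt_pi[None, :]      # U^T D^(1/2)
        self._right = U / sqrt_pi[:, None]       # D^(-1/2) U

    @property
    def n_states(self) -> int:
        return len(self.states)

    def transition_matrix(self, t: float, rate: float = 1.0) -> np.ndarray:
        """P(t) = exp(Q * t * rate); rows sum to 1, entries clamped at 0."""
        if t < 0:
            raise ModelError(f"negative branch length {t}")
        P = (self._right * np.exp(self._eigval * t * rate)) @ self._left
        low = P.min()
        if low < -1e-8:
            raise ModelError(f"transition matrix entry {low:.3e} below tolerance")
        np.clip(P, 0.0, None, out=P)
        return P

    def transition_stack(self, t: float, rates: np.ndarray) -> np.ndarray:
        """P(t * r) for every rate in ``rates``, stacked as (k, n, n)."""
        if t < 0:
            raise ModelError(f"negative branch length {t}")
        ew = np.exp(np.multiply.outer(np.asarray(rates) * t, self._eigval))
        P = (self._right[None, :, :] * ew[:, None, :]) @ self._left
        np.clip(P, 0.0, None, out=P)
        return P

    def state_index(self, state: str) -> int:
        return self.states.index(state)


def transition_matrix(model: RateMatrix, t: float, rate: float = 1.0) -> np.ndarray:
    return model.transition_matrix(t, rate)


# ---------------------------------------------------------------------------
# Empirical amino-acid model (WAG)


def _load_wag() -> tuple[np.ndarray, np.ndarray]:
    text = resources.files("asrpipe.data").joinpath("wag.txt").read_text()
    rows = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    n = 20
    s = np.zeros((n, n))
    for i, line in enumerate(rows[:-1], start=1):
        vals = [float(x) for x in line.split()]
        s[i, : len(vals)] = vals
    s = s + s.T
    freqs = np.array([float(x) for x in rows[-1].split()])
    # permute from the published (PAML) order to alphabetical
    perm = [_PAML_AA_ORDER.index(a) for a in AA_STATES]
    s = s[np.ix_(perm, perm)]
    freqs = freqs[perm]
    freqs = freqs / freqs.sum()
    return s, freqs


_WAG_CACHE: tuple[np.ndarray, np.ndarray] | None = None


def build_empirical_aa(model_name: str = "WAG", frequencies=None) -> RateMatrix:
    """WAG replacement model, optionally with empirical ('+F') frequencies."""
    global _WAG_CACHE
    if model_name.upper() != "WAG":
        raise ModelError(f"unknown empirical amino-acid model {model_name!r}")
    if _WAG_CACHE is None:
        _WAG_CACHE = _load_wag()
    s, own_freqs = _WAG_CACHE
    pi = own_freqs if frequencies is None else np.asarray(frequencies, dtype=float)
    if abs(pi.sum() - 1.0) > 1e-9:
        raise ModelError(f"frequencies sum to {pi.sum():.12f}, not 1")
    name = "WAG" if frequencies is None else "WAG+F"
    return RateMatrix(AA_STATES, s.copy(), pi, name=name)


def empirical_aa_frequencies(alignment) -> np.ndarray:
    """Observed amino-acid frequencies ('+F'), gaps/X excluded, with a small
    pseudocount so no state has frequency zero."""
    counts = np.full(20, 0.1)
    index = {a: i for i, a in enumerate(AA_STATES)}
    for seq in alignment.sequences:
        for ch in seq.residues:
            if ch in index:
                counts[index[ch]] += 1
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# GTR nucleotide model


def build_gtr(exchangeabilities, frequencies) -> RateMatrix:
    """General time-reversible nucleotide model.

    ``exchangeabilities`` are the six rates in the order AC, AG, AT, CG, CT,
    GT; ``frequencies`` is pi over ACGT.
    """
    ex = np.asarray(exchangeabilities, dtype=float)
    if ex.shape != (6,):
        raise ModelError("GTR needs 6 exchangeabilities (AC,AG,AT,CG,CT,GT)")
    if np.any(ex <= 0):
        raise ModelError("GTR exchangeabilities must be positive")
    s = np.zeros((4, 4))
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    for (i, j), v in zip(pairs, ex):
        s[i, j] = s[j, i] = v
    pi = np.asarray(frequencies, dtype=float)
    return RateMatrix(NT_STATES, s, pi, name="GTR")


def jukes_cantor() -> RateMatrix:
    return build_gtr(np.ones(6), np.full(4, 0.25))


# ---------------------------------------------------------------------------
# Codon model (M0-style: kappa, omega)


@dataclass
class CodonModelParams:
    kappa: float = 2.0
    omega: float = 0.5
    codon_frequencies: np.ndarray | None = None  # None -> uniform

    def __post_init__(self) -> None:
        if self.kappa <= 0 or self.omega <= 0:
            raise ModelError("kappa and omega must be positive")
        if self.codon_frequencies is not None:
            pi = np.asarray(self.codon_frequencies, dtype=float)
            if pi.shape != (61,):
                raise ModelError("codon frequencies must cover the 61 sense codons")
            self.codon_frequencies = pi


def build_codon(params: CodonModelParams) -> RateMatrix:
    """Goldman–Yang-style codon model: single-nucleotide steps only, with a
    transition factor kappa and a nonsynonymous factor omega."""
    n = 61
    pi = (
        np.full(n, 1.0 / n)
        if params.codon_frequencies is None
        else params.codon_frequencies
    )
    s = np.zeros((n, n))
    for i, ci in enumerate(CODON_STATES):
        for j in range(i + 1, n):
            cj = CODON_STATES[j]
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            rate = 1.0
            if frozenset(diffs[0]) in TRANSITIONS:
                rate *= params.kappa
            if _CODON_TABLE[ci] != _CODON_TABLE[cj]:
                rate *= params.omega
            s[i, j] = s[j, i] = rate
    return RateMatrix(CODON_STATES, s, pi, name="M0")


def f3x4_frequencies(codon_sequences) -> np.ndarray:
    """F3x4 codon frequencies: product of per-codon-position nucleotide
    frequencies, renormalized over sense codons."""
    counts = np.full((3, 4), 0.1)
    nt_index = {a: i for i, a in enumerate(NT_STATES)}
    for seq in codon_sequences:
        s = seq.residues if hasattr(seq, "residues") else seq
        for i in range(0, len(s) - 2, 3):
            codon = s[i : i + 3]
            if "-" in codon or "N" in codon:
                continue
            for pos, ch in enumerate(codon):
                if ch in nt_index:
                    counts[pos, nt_index[ch]] += 1
    pos_freq = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            pos_freq[0, nt_index[c[0]]]
            * pos_freq[1, nt_index[c[1]]]
            * pos_freq[2, nt_index[c[2]]]
            for c in CODON_STATES
        ]
    )
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# Among-site rate variation


@dataclass
class SiteRateModel:
    """Discrete site-rate mixture with mean rate one.

    ``rates[i]`` applies with probability ``weights[i]``; an invariant class
    (rate 0) is prepended when ``p_invariant`` > 0 and the remaining rates are
    rescaled by 1/(1-p_inv) to keep the mean at one.
    """

    rates: np.ndarray
    weights: np.ndarray
    gamma_shape: float | None = None
    p_invariant: float = 0.0

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ModelError("site-rate weights must sum to 1")
        mean = float(self.rates @ self.weights)
        if abs(mean - 1.0) > 1e-9:
            raise ModelError(f"site-rate mean is {mean:.12f}, not 1")

    @property
    def n_categories(self) -> int:
        return len(self.rates)


def uniform_rates() -> SiteRateModel:
    return SiteRateModel(np.array([1.0]), np.array([1.0]))


def discrete_gamma(alpha: float, k: int = 4, p_invariant: float = 0.0) -> SiteRateModel:
    """Mean-of-slice discrete gamma with k equal-weight categories, optionally
    combined with an invariant class."""
    if alpha <= 0:
        raise ModelError("gamma shape must be positive")
    if k < 1:
        raise ModelError("need at least one rate category")
    if not 0 <= p_invariant < 1:
        raise ModelError("p_invariant must lie in [0,1)")
    if k == 1:
        rates = np.array([1.0])
        weights = np.array([1.0])
    else:
        # category boundaries at the quantiles of Gamma(alpha, rate=alpha)
        edges = gamma_dist.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
        edges = np.concatenate([[0.0], edges, [np.inf]])
        # mean of each slice: k * (F_{alpha+1}(b_hi) - F_{alpha+1}(b_lo))
        upper = gammainc(alpha + 1.0, alpha * edges[1:])
        lower = gammainc(alpha + 1.0, alpha * edges[:-1])
        rates = k * (upper - lower)
        rates = rates / (rates.mean())  # exact renormalization
        weights = np.full(k, 1.0 / k)
    if p_invariant > 0:
        rates = np.concatenate([[0.0], rates / (1.0 - p_invariant)])
        weights = np.concatenate([[p_invariant], weights * (1.0 - p_invariant)])
    return SiteRateModel(rates, weights, gamma_shape=alpha, p_invariant=p_invariant)
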