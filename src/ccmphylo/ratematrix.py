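"""Substitution rate matrices and transition probabilities.

Two reversible models power everything here:

* a Goldman-Yang-style codon model over the 61 sense codons, with
  instantaneous rate q_ij proportional to the target codon frequency pi_j,
  multiplied by kappa for transitions and by omega (dN/dS) for
  nonsynonymous changes; multi-nucleotide changes are forbidden;
* GTR over nucleotides, combined with a discrete-gamma rate mixture for
  among-site rate variation.

Each rate matrix is scaled so the expected substitution rate at
stationarity is one, making branch lengths expected substitutions per
site (per codon for the codon model).  Transition probabilities use the
eigendecomposition of the pi-symmetrised matrix, with an expm fallback.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.linalg import expm
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .genetics import GeneticCode, standard_code

_PURINES = {"A", "G"}


def _is_transition(a: str, b: str) -> bool:
    return a != b and ((a in _PURINES) == (b in _PURINES))


@dataclass(frozen=True)
class CodonModelParams:
    """Parameters of the codon substitution process for one site class."""

    kappa: float
    omega: float
    pi: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if not self.kappa > 0:
            raise ValueError("kappa must be > 0")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        pi = np.asarray(self.pi, dtype=float)
        if pi.ndim != 1 or len(pi) != 61:
            raise ValueError("pi must be a vector over the 61 sense codons")
        if np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-8:
            raise ValueError("pi must be nonnegative and sum to 1")
        object.__setattr__(self, "pi", pi)

    def with_omega(self, omega: float) -> "CodonModelParams":
        return CodonModelParams(self.kappa, omega, self.pi)


@dataclass(frozen=True)
class GTRGammaParams:
    """GTR exchangeabilities/frequencies plus a gamma shape for rate
    variation (discretised into ``ncat`` equal-probability categories)."""

    exchangeabilities: np.ndarray  # order AC, AG, AT, CG, CT, GT
    base_freqs: np.ndarray
    alpha: float = 1.0
    ncat: int = 4

    def __post_init__(self) -> None:
        ex = np.asarray(self.exchangeabilities, dtype=float)
        fr = np.asarray(self.base_freqs, dtype=float)
        if ex.shape != (6,) or np.any(ex <= 0):
            raise ValueError("need 6 positive exchangeabilities")
        if fr.shape != (4,) or np.any(fr < 0) or abs(fr.sum() - 1) > 1e-8:
            raise ValueError("base frequencies must be a distribution over ACGT")
        if not self.alpha > 0:
            raise ValueError("gamma shape must be > 0")
        object.__setattr__(self, "exchangeabilities", ex)
        object.__setattr__(self, "base_freqs", fr)

    @classmethod
    def jukes_cantor_like(cls, alpha: float = 1e6, ncat: int = 4) -> "GTRGammaParams":
        return cls(np.ones(6), np.full(4, 0.25), alpha=alpha, ncat=ncat)


@lru_cache(maxsize=4)
def codon_change_structure(code: GeneticCode):
    """Masks over 61x61 codon pairs: single-nucleotide change, transition,
    nonsynonymous."""
    codons = code.sense_codons
    n = len(codons)
    single = np.zeros((n, n), dtype=bool)
    transition = np.zeros((n, n), dtype=bool)
    nonsyn = np.zeros((n, n), dtype=bool)
    for i, ci in enumerate(codons):
        for j, cj in enumerate(codons):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            single[i, j] = True
            transition[i, j] = _is_transition(*diffs[0])
            nonsyn[i, j] = code.table[ci] != code.table[cj]
    return single, transition, nonsyn


def _scale_generator(Q: np.ndarray, pi: np.ndarray) -> np.ndarray:
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = -(pi * np.diag(Q)).sum()
    if rate <= 0:
        raise ValueError("degenerate rate matrix (zero mean rate)")
    return Q / rate


def _floor_pi(pi: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    if np.any(pi < eps):
        warnings.warn("zero codon frequencies floored to epsilon", stacklevel=3)
        pi = np.maximum(pi, eps)
        pi = pi / pi.sum()
    return pi


def codon_rate_components(
    kappa: float, pi: np.ndarray, code: GeneticCode | None = None
):
    """Synonymous/nonsynonymous parts of the unscaled GY94 generator.

    Returns (A, B, a, b) with Q_raw(omega) = A + omega * B (diagonals
    included) and mean substitution rates a + omega * b at stationarity.
    Site-class mixtures share one scale factor computed from these parts,
    so a class with omega > 1 genuinely accumulates more substitutions.
    """
    code = code or standard_code()
    single, transition, nonsyn = codon_change_structure(code)
    pi = _floor_pi(np.asarray(pi, dtype=float))
    base = np.where(single, pi[None, :], 0.0)
    base = np.where(single & transition, base * kappa, base)
    A = np.where(single & ~nonsyn, base, 0.0)
    B = np.where(single & nonsyn, base, 0.0)
    np.fill_diagonal(A, -A.sum(axis=1))
    np.fill_diagonal(B, -B.sum(axis=1))
    a = -(pi * np.diag(A)).sum()
    b = -(pi * np.diag(B)).sum()
    return A, B, float(a), float(b)


def build_codon_rate_matrix(
    params: CodonModelParams, code: GeneticCode | None = None
) -> np.ndarray:
    """GY94 instantaneous rate matrix, scaled to mean rate 1."""
    A, B, a, b = codon_rate_components(params.kappa, params.pi, code)
    rate = a + params.omega * b
    if rate <= 0:
        raise ValueError("degenerate rate matrix (zero mean rate)")
    return (A + params.omega * B) / rate


def gtr_rate_matrix(params: GTRGammaParams) -> np.ndarray:
    """GTR rate matrix over ACGT, scaled to mean rate 1."""
    ex = params.exchangeabilities
    pi = params.base_freqs
    S = np.zeros((4, 4))
    S[0, 1], S[0, 2], S[0, 3] = ex[0], ex[1], ex[2]
    S[1, 2], S[1, 3] = ex[3], ex[4]
    S[2, 3] = ex[5]
    S = S + S.T
    Q = S * pi[None, :]
    return _scale_generator(Q, _floor_pi(pi))


def discrete_gamma_rates(alpha: float, ncat: int = 4) -> np.ndarray:
    """Mean rates of ``ncat`` equal-probability categories of a
    Gamma(alpha, alpha) distribution; the rates average exactly 1."""
    if ncat < 1:
        raise ValueError("need at least one rate category")
    if ncat == 1:
        return np.ones(1)
    edges = gamma_dist.ppf(np.arange(1, ncat) / ncat, a=alpha, scale=1 / alpha)
    bounds = np.concatenate([[0.0], edges, [np.inf]])
    # mean within each slice via the incomplete-gamma identity
    upper = gammainc(alpha + 1, bounds[1:] * alpha)
    lower = gammainc(alpha + 1, bounds[:-1] * alpha)
    rates = (upper - lower) * ncat
    return rates / rates.mean()


class SpectralMatrix:
    """Eigendecomposition of a reversible generator, for fast P(t).

    The generator is symmetrised as S = D^{1/2} Q D^{-1/2} with
    D = diag(pi), diagonalised once, and P(t) = D^{-1/2} U e^{Lt} U' D^{1/2}
    evaluated per branch length.  Falls back to scipy's expm when the
    symmetrised matrix is not numerically symmetric.
    """

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        self.Q = Q
        pi = _floor_pi(np.asarray(pi, dtype=float))
        sqrt_pi = np.sqrt(pi)
        S = Q * (sqrt_pi[:, None] / sqrt_pi[None, :])
        self._ok = np.max(np.abs(S - S.T)) < 1e-8
        if self._ok:
            lam, U = np.linalg.eigh((S + S.T) / 2)
            self.lam = lam
            self.left = U / sqrt_pi[:, None]  # D^{-1/2} U
            self.right = (U * sqrt_pi[:, None]).T  # U' D^{1/2}

    def probability(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("branch length must be >= 0")
        if not self._ok:
            return expm(self.Q * t)
        P = (self.left * np.exp(self.lam * t)) @ self.right
        np.clip(P, 0.0, None, out=P)
        return P / P.sum(axis=1, keepdims=True)

    def probabilities(self, ts: np.ndarray) -> np.ndarray:
        """P(t) stacked for a vector of branch lengths: (len(ts), n, n)."""
        ts = np.asarray(ts, dtype=float)
        if np.any(ts < 0):
            raise ValueError("branch lengths must be >= 0")
        if not self._ok:
            return np.stack([expm(self.Q * t) for t in ts])
        E = np.exp(np.multiply.outer(ts, self.lam))  # (B, n)
        P = (self.left[None, :, :] * E[:, None, :]) @ self.right
        np.clip(P, 0.0, None, out=P)
        return P / P.sum(axis=2, keepdims=True)


def transition_probabilities(Q: np.ndarray, t: float, pi: np.ndarray | None = None) -> np.ndarray:
    """P(t) = exp(Qt) for a single branch length."""
    if pi is None:
        # stationary distribution from the left null vector
        w, v = np.linalg.eig(Q.T)
        pi = np.real(v[:, np.argmin(np.abs(w))])
        pi = np.abs(pi) / np.abs(pi).sum()
    return SpectralMatrix(Q, pi).probability(t)


def estimate_codon_frequencies_f3x4(aln, code: GeneticCode | None = None) -> np.ndarray:
    """F3x4 codon frequencies: products of position-specific nucleotide
    frequencies, renormalised over sense codons."""
    code = code or standard_code()
    counts = np.zeros((3, 4))
    ntidx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for row in aln.rows:
        for k in range(0, len(row), 3):
            for p in range(3):
                i = ntidx.get(row[k + p])
                if i is not None:
                    counts[p, i] += 1
    if counts.sum() == 0:
        raise ValueError("alignment contains no unambiguous nucleotides")
    # a position with no data falls back to uniform
    for p in range(3):
        if counts[p].sum() == 0:
            counts[p] = 1.0
    freqs = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            freqs[0, ntidx[c[0]]] * freqs[1, ntidx[c[1]]] * freqs[2, ntidx[c[2]]]
            for c in code.sense_codons
        ]
    )
    return pi / pi.sum()


def estimate_codon_frequencies_f1x4(aln, code: GeneticCode | None = None) -> np.ndarray:
    """F1x4: overall nucleotide frequencies used at all three positions."""
    code = code or standard_code()
    ntidx = {"A": 0, "C": 1, "G": 2, "T": 3}
    counts = np.zeros(4)
    for row in aln.rows:
        for ch in row:
            i = ntidx.get(ch)
            if i is not None:
                counts[i] += 1
    if counts.sum() == 0:
        raise ValueError("alignment contains no unambiguous nucleotides")
    f = counts / counts.sum()
    pi = np.array([f[ntidx[c[0]]] * f[ntidx[c[1]]] * f[ntidx[c[2]]] for c in code.sense_codons])
    return pi / pi.sum()


def estimate_codon_frequencies_empirical(aln, code: GeneticCode | None = None) -> np.ndarray:
    """Observed sense-codon frequencies (61 - 1 free parameters)."""
    code = code or standard_code()
    counts = np.zeros(61)
    idx = code.codon_index
    for row in aln.rows:
        for k in range(0, len(row), 3):
            j = idx.get(row[k : k + 3])
            if j is not None:
                counts[j] += 1
    if counts.sum() == 0:
        raise ValueError("alignment contains no sense codons")
    counts += 0.5  # avoid exact zeros
    return counts / counts.sum()


FREQUENCY_ESTIMATORS = {
    "F3x4": (estimate_codon_frequencies_f3x4, 9),
    "F1x4": (estimate_codon_frequencies_f1x4, 3),
    "empirical": (estimate_codon_frequencies_empirical, 60),
}
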