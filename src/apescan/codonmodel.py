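"""Codon substitution model machinery.

Implements the Goldman–Yang style codon model used throughout the scan:
a 61-state (sense codons of the universal code) continuous-time Markov
chain whose instantaneous rates distinguish transitions from
transversions (κ) and nonsynonymous from synonymous changes (ω = dN/dS),
with stationary codon frequencies π estimated from the data (F3x4 by
default, F1x4 and F61 selectable).

Each rate matrix is scaled so that one unit of branch length equals one
expected substitution per codon site under that matrix.  The same
convention is used by the simulator and by every likelihood fit, so
branch lengths are comparable across model classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

NUCLEOTIDES = "TCAG"

# Universal genetic code keyed by codon, stop codons excluded below.
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOP_CODONS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")

#: The 61 sense codons, in TCAG order (codeml's ordering).
SENSE_CODONS: tuple[str, ...] = tuple(
    a + b + c
    for a in NUCLEOTIDES
    for b in NUCLEOTIDES
    for c in NUCLEOTIDES
    if GENETIC_CODE[a + b + c] != "*"
)
N_CODONS = len(SENSE_CODONS)  # 61
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}

_TRANSITION_PAIRS = {frozenset("AG"), frozenset("CT")}


def _is_transition(a: str, b: str) -> bool:
    return frozenset((a, b)) in _TRANSITION_PAIRS


@lru_cache(maxsize=1)
def _neighbor_structure() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Boolean (61,61) masks: single-nucleotide-transition and
    single-nucleotide-transversion pairs; plus the nonsynonymous mask."""
    ts = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    tv = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    nonsyn = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [k for k in range(3) if ci[k] != cj[k]]
            if len(diffs) != 1:
                continue
            k = diffs[0]
            if _is_transition(ci[k], cj[k]):
                ts[i, j] = True
            else:
                tv[i, j] = True
            if GENETIC_CODE[ci] != GENETIC_CODE[cj]:
                nonsyn[i, j] = True
    return ts | tv, np.where(ts, 1.0, 0.0), nonsyn


def build_rate_matrix(
    kappa: float, omega: float, pi: np.ndarray, scale: str = "unit"
) -> np.ndarray:
    """Instantaneous rate matrix Q of the codon model.

    q_ij = π_j · κ^[transition] · ω^[nonsynonymous] for codon pairs that
    differ at exactly one position, 0 for pairs differing at more than
    one, and the diagonal makes rows sum to zero.

    Scaling (the ω of the scaling class):

    * ``scale="unit"`` — Q itself is rescaled so the expected number of
      substitutions per unit time is 1 at stationarity (−Σ_i π_i q_ii = 1).
    * ``scale="neutral"`` — Q is divided by the stationary rate of the
      *neutral* (ω = 1) matrix at the same κ and π.  All site classes of
      a mixture then share one time scale: a unit branch length is one
      expected substitution for a neutral site, and classes with ω > 1
      genuinely evolve faster.  The likelihood engine and the simulator
      both use this convention.

    Parameters
    ----------
    kappa : transition/transversion rate ratio, > 0.
    omega : dN/dS ratio, ≥ 0.
    pi : stationary codon frequencies, shape (61,), summing to 1.
    """
    if kappa <= 0:
        raise ValueError(f"kappa must be > 0, got {kappa}")
    if omega < 0:
        raise ValueError(f"omega must be >= 0, got {omega}")
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (N_CODONS,):
        raise ValueError(f"pi must have shape ({N_CODONS},)")
    if np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-9:
        raise ValueError("pi must be nonnegative and sum to 1")
    single, is_ts, nonsyn = _neighbor_structure()
    rates = np.where(single, 1.0, 0.0)
    rates *= np.where(is_ts > 0, kappa, 1.0)
    rates = np.where(nonsyn, rates * omega, rates)
    q = rates * pi[np.newaxis, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    if scale == "unit":
        factor = -np.dot(pi, np.diag(q))
    elif scale == "neutral":
        factor = neutral_rate(kappa, pi)
    else:
        raise ValueError(f"unknown scale {scale!r}")
    if factor <= 0:
        raise ValueError("degenerate rate matrix (zero total rate)")
    return q / factor


def neutral_rate(kappa: float, pi: np.ndarray) -> float:
    """Stationary substitution rate of the unnormalised ω = 1 matrix."""
    single, is_ts, _ = _neighbor_structure()
    rates = np.where(single, 1.0, 0.0) * np.where(is_ts > 0, kappa, 1.0)
    flux = pi[:, None] * rates * pi[None, :]
    return float(flux.sum())


@dataclass
class SpectralQ:
    """Eigendecomposition of a reversible Q, for cheap P(t) at many t.

    A reversible Q with stationary π satisfies D^{1/2} Q D^{-1/2}
    symmetric (D = diag π), so Q = A Λ A⁻¹ with A = D^{-1/2} U.
    """

    evals: np.ndarray          # (61,)
    right: np.ndarray          # A, (61, 61)
    left: np.ndarray           # A⁻¹, (61, 61)

    @classmethod
    def from_rates(cls, kappa: float, omega: float, pi: np.ndarray,
                   scale: str = "unit") -> "SpectralQ":
        q = build_rate_matrix(kappa, omega, pi, scale=scale)
        return cls.from_q(q, pi)

    @classmethod
    def from_q(cls, q: np.ndarray, pi: np.ndarray) -> "SpectralQ":
        # Guard π=0 states (possible under F3x4 on sparse data): the
        # symmetrised form needs strictly positive π, so floor tiny values.
        pi = np.maximum(np.asarray(pi, dtype=float), 1e-12)
        sqrt_pi = np.sqrt(pi)
        b = q * sqrt_pi[:, None] / sqrt_pi[None, :]
        b = (b + b.T) / 2.0
        evals, u = np.linalg.eigh(b)
        right = u / sqrt_pi[:, None]
        left = u.T * sqrt_pi[None, :]
        return cls(evals=evals, right=right, left=left)

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to 1, entries clipped at 0."""
        if t < 0:
            raise ValueError(f"branch length must be >= 0, got {t}")
        p = (self.right * np.exp(self.evals * t)) @ self.left
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=1, keepdims=True)
        return p

    def transition_matrices(self, ts: np.ndarray) -> np.ndarray:
        """Stacked P(t) for a vector of branch lengths, shape (len(ts), 61, 61)."""
        ts = np.asarray(ts, dtype=float)
        if np.any(ts < 0):
            raise ValueError("branch lengths must be >= 0")
        expo = np.exp(np.multiply.outer(ts, self.evals))       # (n, 61)
        p = (self.right[None, :, :] * expo[:, None, :]) @ self.left
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=2, keepdims=True)
        return p


def transition_probabilities(q: np.ndarray, t: float, pi: np.ndarray | None = None) -> np.ndarray:
    """P(t) = exp(Qt) for a single branch length.

    Uses the spectral route when π is supplied (reversible Q), else a
    direct matrix exponential.
    """
    if t < 0:
        raise ValueError(f"branch length must be >= 0, got {t}")
    if pi is not None:
        return SpectralQ.from_q(q, pi).transition_matrix(t)
    from scipy.linalg import expm

    return expm(q * t)


# ---------------------------------------------------------------------------
# Equilibrium codon frequency estimators
# ---------------------------------------------------------------------------

def f61_frequencies(codon_counts: np.ndarray) -> np.ndarray:
    """Empirical codon frequencies with a small pseudo-count."""
    counts = np.asarray(codon_counts, dtype=float) + 0.5
    return counts / counts.sum()


def f1x4_frequencies(nuc_counts: np.ndarray) -> np.ndarray:
    """Codon frequencies from overall nucleotide frequencies (F1x4)."""
    f = np.asarray(nuc_counts, dtype=float) + 0.5
    f = f / f.sum()
    return _product_frequencies(f, f, f)


def f3x4_frequencies(nuc_counts_by_pos: np.ndarray) -> np.ndarray:
    """Codon frequencies from position-specific nucleotide frequencies (F3x4).

    Parameters
    ----------
    nuc_counts_by_pos : shape (3, 4) counts of T,C,A,G at each codon position.
    """
    f = np.asarray(nuc_counts_by_pos, dtype=float) + 0.5
    f = f / f.sum(axis=1, keepdims=True)
    return _product_frequencies(f[0], f[1], f[2])


def _product_frequencies(f1: np.ndarray, f2: np.ndarray, f3: np.ndarray) -> np.ndarray:
    nuc_idx = {n: i for i, n in enumerate(NUCLEOTIDES)}
    pi = np.array(
        [f1[nuc_idx[c[0]]] * f2[nuc_idx[c[1]]] * f3[nuc_idx[c[2]]] for c in SENSE_CODONS]
    )
    return pi / pi.sum()


def uniform_frequencies() -> np.ndarray:
    return np.full(N_CODONS, 1.0 / N_CODONS)
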