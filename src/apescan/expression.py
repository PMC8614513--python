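"""Tissue-specificity (τ) and expression-level comparison of PSG/paralog pairs.

Expression is measured as log2(TPM + 1).  Tissue specificity uses the
τ index:

    τ = Σ_i (1 − x_i / max(x)) / (n − 1)

on the log-transformed profile x over n tissues: τ = 0 for perfectly
uniform expression, τ = 1 for single-tissue expression, undefined when
the gene is silent everywhere.  Each PSG from a multigene family is
paired with its most similar non-PSG paralog (highest global protein
identity; ties broken by longer alignment, then smaller gene id) and
the pairs are compared on τ and on mean expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Genes × tissues TPM table with a one-shot log-transform flag."""

    values: pd.DataFrame
    log_transformed: bool = False

    def __post_init__(self):
        if (self.values.to_numpy() < 0).any():
            raise ValueError("TPM values must be nonnegative")
        if self.values.shape[1] < 2:
            raise ValueError("need at least 2 tissues")


def log_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2(TPM + 1); refuses to transform twice."""
    if matrix.log_transformed:
        raise ValueError("matrix is already log-transformed")
    return ExpressionMatrix(values=np.log2(matrix.values + 1.0),
                            log_transformed=True)


def tau(expression_vector) -> float | None:
    """τ tissue-specificity index; None (undefined) if all-zero."""
    x = np.asarray(expression_vector, dtype=float)
    if x.size < 2:
        raise ValueError("tau needs at least 2 tissues")
    if np.any(x < 0):
        raise ValueError("expression values must be nonnegative")
    top = x.max()
    if top == 0:
        return None
    return float(np.sum(1.0 - x / top) / (x.size - 1))


def tau_table(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene τ and mean expression (expects the log-transformed matrix)."""
    if not matrix.log_transformed:
        raise ValueError("compute tau on the log-transformed matrix")
    rows = []
    for gene, profile in matrix.values.iterrows():
        rows.append({
            "gene_id": gene,
            "tau": tau(profile.to_numpy()),
            "mean_expression": float(profile.mean()),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Paralog pairing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParalogPair:
    psg: str
    paralog: str
    identity: float
    tau_psg: float | None
    tau_paralog: float | None
    mean_psg: float
    mean_paralog: float


def _global_identity(seq_a: str, seq_b: str) -> tuple[float, int]:
    """(matches / alignment length, alignment length) of a global alignment."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    alignment = aligner.align(seq_a.replace("*", "X"), seq_b.replace("*", "X"))[0]
    matches = 0
    length = 0
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        length += a1 - a0
        matches += sum(
            1 for x, y in zip(seq_a[a0:a1], seq_b[b0:b1]) if x == y
        )
    total_len = alignment.length
    return (matches / total_len if total_len else 0.0), total_len


def closest_paralog(
    psg: str,
    family_members: list[str],
    proteins: dict[str, str],
    psg_set: set[str],
) -> tuple[str, float] | None:
    """Most similar non-PSG family member by global protein identity.

    Ties break toward the longer alignment, then the lexicographically
    smaller gene id.  Returns None (logged) when no eligible paralog
    exists.
    """
    candidates = [g for g in family_members if g != psg and g not in psg_set]
    if not candidates:
        logger.info("PSG %s has no eligible non-PSG paralog", psg)
        return None
    scored = []
    for gene in sorted(candidates):
        identity, aln_len = _global_identity(proteins[psg], proteins[gene])
        scored.append((identity, aln_len, gene))
    scored.sort(key=lambda t: (-t[0], -t[1], t[2]))
    best = scored[0]
    return best[2], best[0]


def build_pairs(
    psgs: list[str],
    family_map: pd.DataFrame,
    proteins: dict[str, str],
    tau_by_gene: dict[str, float | None],
    mean_by_gene: dict[str, float],
) -> list[ParalogPair]:
    psg_set = set(psgs)
    fam_of = dict(zip(family_map.gene_id, family_map.family_id))
    members: dict[str, list[str]] = {}
    for gene, fam in fam_of.items():
        members.setdefault(fam, []).append(gene)
    pairs = []
    for psg in sorted(psg_set):
        fam = fam_of.get(psg)
        if fam is None:
            logger.warning("PSG %s missing from family map", psg)
            continue
        hit = closest_paralog(psg, members[fam], proteins, psg_set)
        if hit is None:
            continue
        paralog, identity = hit
        pairs.append(ParalogPair(
            psg=psg, paralog=paralog, identity=identity,
            tau_psg=tau_by_gene.get(psg),
            tau_paralog=tau_by_gene.get(paralog),
            mean_psg=mean_by_gene[psg],
            mean_paralog=mean_by_gene[paralog],
        ))
    return pairs


def compare_pairs(pairs: list[ParalogPair]) -> tuple[pd.DataFrame, dict]:
    """Per-pair Δτ / Δmean and counts of pairs where the PSG is higher.

    "Higher" is a strict inequality; pairs with an undefined τ on either
    side are excluded from the τ count (logged) but kept for the mean.
    """
    rows = []
    n_tau_higher = n_tau_compared = n_mean_higher = 0
    for pair in pairs:
        d_tau = None
        if pair.tau_psg is not None and pair.tau_paralog is not None:
            d_tau = pair.tau_psg - pair.tau_paralog
            n_tau_compared += 1
            if d_tau > 0:
                n_tau_higher += 1
        else:
            logger.info("pair (%s, %s) lacks defined tau on one side",
                        pair.psg, pair.paralog)
        d_mean = pair.mean_psg - pair.mean_paralog
        if d_mean > 0:
            n_mean_higher += 1
        rows.append({
            "psg": pair.psg, "paralog": pair.paralog,
            "identity": pair.identity,
            "tau_psg": pair.tau_psg, "tau_paralog": pair.tau_paralog,
            "delta_tau": d_tau,
            "mean_psg": pair.mean_psg, "mean_paralog": pair.mean_paralog,
            "delta_mean": d_mean,
        })
    summary = {
        "n_pairs": len(pairs),
        "n_tau_compared": n_tau_compared,
        "n_psg_higher_tau": n_tau_higher,
        "n_psg_higher_mean": n_mean_higher,
    }
    columns = ["psg", "paralog", "identity", "tau_psg", "tau_paralog",
               "delta_tau", "mean_psg", "mean_paralog", "delta_mean"]
    return pd.DataFrame(rows, columns=columns), summary
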