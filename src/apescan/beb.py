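"""Bayes empirical Bayes posteriors for positively selected sites.

After the alternative branch-site fit, each alignment column receives
the posterior probability that it belongs to a foreground-selected
class (2a or 2b).  Rather than plugging in the point estimates of
(p0, p1, ω0, ω2), the posterior integrates over a discrete grid prior
on those parameters, weighting each grid point by the likelihood of the
whole alignment — the empirical-Bayes treatment of parameter
uncertainty.  κ and the branch lengths are held at their MLEs.

Grid (fixed, documented here as the package constant):
  * (p0, p1): the 45 points ((i+0.5)/10, (j+0.5)/10) with i+j ≤ 8 —
    a uniform triangular grid over the proportion simplex;
  * ω0: the 10 midpoints (i+0.5)/10 of (0, 1);
  * ω2: the 10 midpoints 1 + (i+0.5) of (1, 11).
All grid points carry equal prior mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .alignment import CodonAlignment
from .fit import FitResult, estimate_pi
from .likelihood import TreeLikelihood
from .trees import LabeledTree

_GRID_D = 10
OMEGA0_GRID = (np.arange(_GRID_D) + 0.5) / _GRID_D
OMEGA2_GRID = 1.0 + (np.arange(_GRID_D) + 0.5)
P_GRID = [
    ((i + 0.5) / _GRID_D, (j + 0.5) / _GRID_D)
    for i in range(_GRID_D)
    for j in range(_GRID_D)
    if i + j <= _GRID_D - 2
]


@dataclass
class BEBResult:
    """Per-column posterior of foreground selection and the >0.95 site list."""

    posteriors: np.ndarray          # (n_columns,)
    selected_sites: tuple[int, ...]  # 1-based aa columns
    threshold: float

    def __post_init__(self):
        if np.any(self.posteriors < -1e-9) or np.any(self.posteriors > 1 + 1e-9):
            raise ValueError("posteriors must lie in [0,1]")


def beb_site_posteriors(
    alignment: CodonAlignment,
    tree: LabeledTree,
    alt_fit: FitResult,
    pi: np.ndarray | None = None,
    engine: TreeLikelihood | None = None,
    threshold: float = 0.95,
) -> BEBResult:
    """Empirical-Bayes posterior of classes 2a+2b at every aa column.

    ``alt_fit`` supplies κ (and must come from a converged alternative
    fit on the same labeled tree).  Sites with posterior strictly above
    ``threshold`` form the selected-site list.
    """
    if not alt_fit.converged:
        raise ValueError("BEB requires a converged alternative fit")
    if pi is None:
        pi = estimate_pi(alignment)
    if engine is None:
        engine = TreeLikelihood(alignment, tree, pi)
    kappa = alt_fit.kappa
    # use the alternative fit's branch lengths (it may have re-estimated
    # the foreground edge)
    lengths = (alt_fit.tree.length_vector()
               if alt_fit.tree is not None else tree.length_vector())
    fg = tree.foreground_nodes()
    counts = engine.pattern_weights
    n_pat = engine.n_patterns

    # Class-conditional site likelihoods on the grid (patterns, not columns).
    f0 = np.stack([
        engine.class_site_likelihoods(kappa, w0, w0, lengths, fg)
        for w0 in OMEGA0_GRID
    ])                                                     # (10, n_pat)
    f1 = engine.class_site_likelihoods(kappa, 1.0, 1.0, lengths, fg)
    f2a = np.stack([
        np.stack([
            engine.class_site_likelihoods(kappa, w0, w2, lengths, fg)
            for w2 in OMEGA2_GRID
        ])
        for w0 in OMEGA0_GRID
    ])                                                     # (10, 10, n_pat)
    f2b = np.stack([
        engine.class_site_likelihoods(kappa, 1.0, w2, lengths, fg)
        for w2 in OMEGA2_GRID
    ])                                                     # (10, n_pat)

    p_arr = np.asarray(P_GRID)                             # (45, 2)
    s = p_arr.sum(axis=1)
    q = p_arr[:, 0] / s
    w0_ = q * s
    w1_ = (1 - q) * s
    w2a_ = q * (1 - s)
    w2b_ = (1 - q) * (1 - s)

    # mix[p, i, j, h] and sel[p, i, j, h]
    mix = (
        w0_[:, None, None, None] * f0[None, :, None, :]
        + w1_[:, None, None, None] * f1[None, None, None, :]
        + w2a_[:, None, None, None] * f2a[None, :, :, :]
        + w2b_[:, None, None, None] * f2b[None, None, :, :]
    )
    sel = (
        w2a_[:, None, None, None] * f2a[None, :, :, :]
        + w2b_[:, None, None, None] * f2b[None, None, :, :]
    )
    mix = np.maximum(mix, 1e-300)
    log_mix = np.log(mix)
    loglik_grid = log_mix @ counts                          # (45, 10, 10)
    log_post_grid = loglik_grid - logsumexp(loglik_grid)
    grid_weights = np.exp(log_post_grid)

    post_sel_pat = np.einsum(
        "pij,pijh->h", grid_weights, sel / mix, optimize=True
    )                                                       # (n_pat,)
    post_columns = np.clip(post_sel_pat[engine.pattern_of_column], 0.0, 1.0)
    selected = tuple(int(c) for c in np.where(post_columns > threshold)[0] + 1)
    return BEBResult(posteriors=post_columns, selected_sites=selected,
                     threshold=threshold)
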