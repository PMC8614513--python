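"""Phylogenetic likelihood for codon alignments.

Felsenstein pruning over the 61 sense-codon states, with site-pattern
compression and a per-(κ, ω) spectral cache so that repeated likelihood
evaluations during optimisation stay cheap.  Gap and masked (N-containing)
cells are treated as missing data: the tip partial is summed over all 61
states for that sequence only, never by deleting the column.

A *site class* is a pair of dN/dS values (background ω, foreground ω)
applied to background and foreground branches respectively; a mixture of
classes with weights gives the branch-site models used by the scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import CodonAlignment
from .codonmodel import N_CODONS, SpectralQ
from .trees import LabeledTree


@dataclass(frozen=True)
class SiteClass:
    """One mixture component: (weight, background ω, foreground ω)."""

    weight: float
    omega_background: float
    omega_foreground: float


class TreeLikelihood:
    """Pruning likelihood of one codon alignment on one labeled tree.

    Branch lengths and the foreground set are supplied per call, so one
    instance serves the M0, branch-site and relaxation fits of a gene.
    Per-class conditional site likelihoods are cached by
    (κ, ω_bg, ω_fg, branch lengths, foreground), which makes mixture-weight
    optimisation and finite-difference gradients nearly free for the
    parameters they do not touch.
    """

    _MAX_CACHE = 4096

    def __init__(self, alignment: CodonAlignment, tree: LabeledTree,
                 pi: np.ndarray):
        if tuple(alignment.taxa) != tuple(tree.taxa):
            order = [alignment.taxa.index(t) for t in tree.taxa]
            codes = alignment.codes[order]
        else:
            codes = alignment.codes
        self.tree = tree
        self.pi = np.asarray(pi, dtype=float)
        # site-pattern compression
        patterns, inverse, counts = np.unique(
            codes.T, axis=0, return_inverse=True, return_counts=True
        )
        self.patterns = patterns.T            # (n_taxa, n_patterns)
        self.pattern_of_column = inverse      # (n_columns,)
        self.pattern_weights = counts.astype(float)
        self.n_columns = codes.shape[1]
        self.n_patterns = self.patterns.shape[1]
        self._tip_missing = self.patterns < 0  # gap or mask
        self._children = {
            node: tree.children(node)
            for node in range(tree.n_tips, tree.n_nodes)
        }
        self._spectral_cache: dict[tuple, SpectralQ] = {}
        self._class_cache: dict[tuple, np.ndarray] = {}
        self._p_cache: dict[tuple, np.ndarray] = {}

    # -- caches ------------------------------------------------------------
    def spectral(self, kappa: float, omega: float) -> SpectralQ:
        key = (round(kappa, 10), round(omega, 10))
        hit = self._spectral_cache.get(key)
        if hit is None:
            if len(self._spectral_cache) > self._MAX_CACHE:
                self._spectral_cache.clear()
            hit = SpectralQ.from_rates(kappa, omega, self.pi, scale="neutral")
            self._spectral_cache[key] = hit
        return hit

    def class_site_likelihoods(
        self,
        kappa: float,
        omega_background: float,
        omega_foreground: float | None = None,
        lengths: np.ndarray | None = None,
        foreground_nodes: frozenset[int] | None = None,
    ) -> np.ndarray:
        """Per-pattern likelihood under a single (ω_bg, ω_fg) class."""
        if omega_foreground is None:
            omega_foreground = omega_background
        if lengths is None:
            lengths = self.tree.length_vector()
        if foreground_nodes is None:
            foreground_nodes = self.tree.foreground_nodes()
        lengths = np.asarray(lengths, dtype=float)
        key = (
            round(kappa, 10), round(omega_background, 10),
            round(omega_foreground, 10), lengths.tobytes(), foreground_nodes,
        )
        hit = self._class_cache.get(key)
        if hit is None:
            if len(self._class_cache) > self._MAX_CACHE:
                self._class_cache.clear()
            hit = self._prune(kappa, omega_background, omega_foreground,
                              lengths, foreground_nodes)
            self._class_cache[key] = hit
        return hit

    # -- pruning -----------------------------------------------------------
    def _prune(self, kappa, omega_bg, omega_fg, lengths, fg_nodes) -> np.ndarray:
        tree = self.tree
        n_edges = tree.n_nodes - 1
        fg_mask = np.zeros(n_edges, dtype=bool)
        for node in fg_nodes:
            fg_mask[node] = True
        bg_idx = np.where(~fg_mask)[0]
        fg_idx = np.where(fg_mask)[0]
        lengths_key = lengths.tobytes()
        p_of_edge: dict[int, np.ndarray] = {}
        if bg_idx.size:
            stack = self._edge_p(kappa, omega_bg, lengths, bg_idx, lengths_key)
            for pos, edge in enumerate(bg_idx):
                p_of_edge[int(edge)] = stack[pos]
        if fg_idx.size:
            stack = self._edge_p(kappa, omega_fg, lengths, fg_idx, lengths_key)
            for pos, edge in enumerate(fg_idx):
                p_of_edge[int(edge)] = stack[pos]

        # partials in (n_patterns, n_states) orientation: row gathers for
        # tips and (n_pat, 61) @ (61, 61) matmuls for internal children
        partial: dict[int, np.ndarray] = {}
        for node in range(tree.n_tips, tree.n_nodes):
            lik = None
            for child in self._children[node]:
                if child < tree.n_tips:
                    contrib = self._tip_contribution(p_of_edge[child], child)
                else:
                    contrib = partial.pop(child) @ p_of_edge[child].T
                lik = contrib if lik is None else lik * contrib
            partial[node] = lik
        root_partial = partial[tree.root]
        return root_partial @ self.pi  # (n_patterns,)

    def _edge_p(self, kappa, omega, lengths, idx, lengths_key) -> np.ndarray:
        key = (round(kappa, 10), round(omega, 10), lengths_key, idx.tobytes())
        hit = self._p_cache.get(key)
        if hit is None:
            if len(self._p_cache) > self._MAX_CACHE:
                self._p_cache.clear()
            hit = self.spectral(kappa, omega).transition_matrices(lengths[idx])
            self._p_cache[key] = hit
        return hit

    def _tip_contribution(self, p: np.ndarray, tip: int) -> np.ndarray:
        codes = self.patterns[tip]
        observed = codes >= 0
        if observed.all():
            return p.T[codes]
        contrib = np.ones((self.n_patterns, N_CODONS))
        contrib[observed] = p.T[codes[observed]]
        return contrib

    # -- public likelihoods -------------------------------------------------
    def mixture_site_loglik(
        self,
        kappa: float,
        classes: list[SiteClass],
        lengths: np.ndarray | None = None,
        foreground_nodes: frozenset[int] | None = None,
        per_column: bool = False,
    ) -> tuple[float, np.ndarray]:
        """Total and per-site log-likelihood of a site-class mixture.

        Returns ``(total, per_site)`` where ``per_site`` is per pattern
        unless ``per_column`` expands it to alignment columns.
        """
        weights = np.array([c.weight for c in classes])
        if np.any(weights < -1e-12) or abs(weights.sum() - 1.0) > 1e-9:
            raise ValueError("class weights must be a probability vector")
        f = np.zeros(self.n_patterns)
        for c in classes:
            if c.weight <= 0:
                continue
            f += c.weight * self.class_site_likelihoods(
                kappa, c.omega_background, c.omega_foreground,
                lengths, foreground_nodes)
        logf = np.log(np.maximum(f, 1e-300))
        total = float(self.pattern_weights @ logf)
        per_site = logf[self.pattern_of_column] if per_column else logf
        return total, per_site

    def all_missing_columns(self) -> np.ndarray:
        """1-based indices of columns where every sequence is gap/masked."""
        allmiss = self._tip_missing.all(axis=0)
        return np.where(allmiss[self.pattern_of_column])[0] + 1


def site_log_likelihood(
    alignment: CodonAlignment,
    tree: LabeledTree,
    classes: list[SiteClass],
    kappa: float,
    pi: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Convenience wrapper: per-column and total mixture log-likelihood."""
    engine = TreeLikelihood(alignment, tree, pi)
    total, per_site = engine.mixture_site_loglik(kappa, classes, per_column=True)
    return total, per_site
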