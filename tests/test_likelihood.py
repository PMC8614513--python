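"""Pruning likelihood against exhaustive-enumeration oracles."""

import itertools

import numpy as np
import pytest

from apescan.alignment import CodonAlignment
from apescan.codonmodel import N_CODONS, SpectralQ
from apescan.likelihood import SiteClass, TreeLikelihood, site_log_likelihood
from apescan.trees import LabeledTree


def enumeration_loglik(alignment, tree, classes, kappa, pi):
    """Sum over all internal-state assignments — independent oracle."""
    mats = {}

    def P(omega, t):
        if (omega, t) not in mats:
            mats[(omega, t)] = SpectralQ.from_rates(
                kappa, omega, pi, scale="neutral").transition_matrix(t)
        return mats[(omega, t)]

    fg = tree.foreground_nodes()
    internal = list(range(tree.n_tips, tree.n_nodes))
    per_site = []
    for col in range(alignment.n_columns):
        f = 0.0
        for cl in classes:
            total = 0.0
            for states in itertools.product(range(N_CODONS),
                                            repeat=len(internal)):
                assign = dict(zip(internal, states))
                p = pi[assign[tree.root]]
                for node in range(tree.n_nodes - 1):
                    omega = (cl.omega_foreground if node in fg
                             else cl.omega_background)
                    parent_state = assign[tree.parent[node]]
                    if node < tree.n_tips:
                        child_state = alignment.codes[node, col]
                        if child_state < 0:
                            continue  # missing: sums to 1
                        p *= P(omega, tree.lengths[node])[parent_state,
                                                          child_state]
                    else:
                        p *= P(omega, tree.lengths[node])[parent_state,
                                                          assign[node]]
                total += p
            f += cl.weight * total
        per_site.append(np.log(f))
    return np.array(per_site)


MIX = [SiteClass(0.6, 0.2, 0.2), SiteClass(0.4, 1.0, 5.0)]


class TestEnumerationOracle:
    def test_trifurcating_root(self, three_taxon_tree, tiny_alignment,
                               uniform_pi):
        total, per_site = site_log_likelihood(
            tiny_alignment, three_taxon_tree, MIX, 2.0, uniform_pi)
        oracle = enumeration_loglik(tiny_alignment, three_taxon_tree, MIX,
                                    2.0, uniform_pi)
        np.testing.assert_allclose(per_site, oracle, atol=1e-8)
        assert total == pytest.approx(oracle.sum(), abs=1e-8)

    def test_two_internal_nodes(self, uniform_pi):
        # ((a,b),c): cherry node + root -> 61^2 enumeration
        tree = LabeledTree(
            taxa=("a", "b", "c"), parent=(3, 3, 4, 4, -1),
            lengths=(0.15, 0.25, 0.4, 0.2, 0.0),
            branch_names={"a": 0, "b": 1, "c": 2, "ab": 3},
            foreground=frozenset({"b"}),
        )
        aln = CodonAlignment.from_strings(
            {"a": "ATGAAA", "b": "ACGCAA", "c": "ATGCCC"})
        total, per_site = site_log_likelihood(aln, tree, MIX, 1.7, uniform_pi)
        oracle = enumeration_loglik(aln, tree, MIX, 1.7, uniform_pi)
        np.testing.assert_allclose(per_site, oracle, atol=1e-8)

    def test_with_gap_and_masked_cells(self, three_taxon_tree, uniform_pi):
        aln = CodonAlignment.from_strings(
            {"a": "ATG---TTT", "b": "ATGAAGNNN", "c": "ATGCCCTTT"})
        total, per_site = site_log_likelihood(
            aln, three_taxon_tree, MIX, 2.0, uniform_pi)
        oracle = enumeration_loglik(aln, three_taxon_tree, MIX, 2.0,
                                    uniform_pi)
        np.testing.assert_allclose(per_site, oracle, atol=1e-8)


class TestDegenerateCases:
    def test_identical_sequences_zero_lengths(self, uniform_pi):
        tree = LabeledTree(
            taxa=("a", "b", "c"), parent=(3, 3, 3, -1),
            lengths=(0.0, 0.0, 0.0, 0.0),
            branch_names={"a": 0, "b": 1, "c": 2},
        )
        aln = CodonAlignment.from_strings(
            {"a": "ATGAAA", "b": "ATGAAA", "c": "ATGAAA"})
        total, per_site = site_log_likelihood(
            aln, tree, [SiteClass(1.0, 0.5, 0.5)], 2.0, uniform_pi)
        # with t=0 everywhere the site likelihood is just pi(observed codon)
        expected = sum(np.log(uniform_pi[aln.codes[0, j]])
                       for j in range(aln.n_columns))
        assert total == pytest.approx(expected, abs=1e-10)

    def test_degenerate_mixture_equals_single_class(self, three_taxon_tree,
                                                    tiny_alignment,
                                                    uniform_pi):
        single, _ = site_log_likelihood(
            tiny_alignment, three_taxon_tree,
            [SiteClass(1.0, 0.3, 0.3)], 2.0, uniform_pi)
        padded, _ = site_log_likelihood(
            tiny_alignment, three_taxon_tree,
            [SiteClass(1.0, 0.3, 0.3), SiteClass(0.0, 1.0, 8.0)],
            2.0, uniform_pi)
        assert single == pytest.approx(padded, abs=1e-12)

    def test_all_gap_column_contributes_zero_and_flagged(
            self, three_taxon_tree, uniform_pi):
        aln = CodonAlignment.from_strings(
            {"a": "ATG---", "b": "ATG---", "c": "ATG---"})
        engine = TreeLikelihood(aln, three_taxon_tree, uniform_pi)
        total, per_site = engine.mixture_site_loglik(
            2.0, [SiteClass(1.0, 0.5, 0.5)], per_column=True)
        assert per_site[1] == pytest.approx(0.0, abs=1e-12)
        assert list(engine.all_missing_columns()) == [2]


class TestInvariances:
    def test_taxon_reordering(self, three_taxon_tree, uniform_pi):
        seqs = {"a": "ATGAAATTT", "b": "ATGAAGTTC", "c": "ATGCCCTTT"}
        fwd = CodonAlignment.from_strings(seqs)
        rev = CodonAlignment.from_strings(dict(reversed(list(seqs.items()))))
        t1, _ = site_log_likelihood(fwd, three_taxon_tree, MIX, 2.0,
                                    uniform_pi)
        t2, _ = site_log_likelihood(rev, three_taxon_tree, MIX, 2.0,
                                    uniform_pi)
        assert t1 == pytest.approx(t2, abs=1e-10)

    def test_rerooting_along_unrooted_topology(self, uniform_pi):
        # same unrooted 3-taxon tree rooted at the internal node vs at a
        # bifurcation splitting edge c (lengths preserved, fg on edge a)
        aln = CodonAlignment.from_strings(
            {"a": "ATGAAATTT", "b": "ATGAAGTTC", "c": "ATGCCCTTT"})
        tri = LabeledTree(
            taxa=("a", "b", "c"), parent=(3, 3, 3, -1),
            lengths=(0.2, 0.3, 0.5, 0.0),
            branch_names={"a": 0, "b": 1, "c": 2},
            foreground=frozenset({"a"}))
        # root placed on edge c, splitting 0.5 into 0.1 + 0.4
        split = LabeledTree(
            taxa=("a", "b", "c"), parent=(3, 3, 4, 4, -1),
            lengths=(0.2, 0.3, 0.4, 0.1, 0.0),
            branch_names={"a": 0, "b": 1, "c": 2, "ab": 3},
            foreground=frozenset({"a"}))
        t1, _ = site_log_likelihood(aln, tri, MIX, 2.0, uniform_pi)
        t2, _ = site_log_likelihood(aln, split, MIX, 2.0, uniform_pi)
        assert t1 == pytest.approx(t2, abs=1e-8)

    def test_pattern_compression_consistency(self, selected_alignment,
                                             ape_tree, uniform_pi):
        aln, _ = selected_alignment
        engine = TreeLikelihood(aln, ape_tree.with_foreground("human"),
                                uniform_pi)
        assert engine.n_patterns <= engine.n_columns
        total, per_col = engine.mixture_site_loglik(2.0, MIX, per_column=True)
        assert len(per_col) == aln.n_columns
        assert total == pytest.approx(
            per_col.sum(), rel=1e-12)

    def test_invalid_weights_rejected(self, three_taxon_tree, tiny_alignment,
                                      uniform_pi):
        with pytest.raises(ValueError):
            site_log_likelihood(tiny_alignment, three_taxon_tree,
                                [SiteClass(0.7, 0.2, 0.2)], 2.0, uniform_pi)
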