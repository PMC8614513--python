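"""Synthetic-data generator: contracts, determinism, generative consistency."""

import warnings

import numpy as np
import pandas as pd
import pytest

from apescan.alignment import GAP_CODE, GeneModel
from apescan.fixation import VariantRecord, is_site_fixed
from apescan.simulate import (
    SimulationSpec,
    inject_gaps,
    n_psg_genes,
    simulate_codon_alignment,
    simulate_column_scores,
    simulate_expression,
    simulate_ortholog_set,
    simulate_relax_alignment,
    simulate_variants,
    write_dataset,
)
from apescan.trees import LabeledTree
from apescan.expression import tau


class TestCodonAlignmentSimulation:
    def test_dimension_contract(self, ape_tree):
        spec = SimulationSpec(tree=ape_tree.with_foreground("human"),
                              n_codons=300, seed=1)
        aln, labels = simulate_codon_alignment(spec)
        assert aln.codes.shape == (6, 300)
        assert labels.shape == (300,)

    def test_determinism_under_seed(self, ape_tree):
        spec = SimulationSpec(tree=ape_tree.with_foreground("human"),
                              n_codons=60, seed=7)
        a1, l1 = simulate_codon_alignment(spec)
        a2, l2 = simulate_codon_alignment(spec)
        assert np.array_equal(a1.codes, a2.codes)
        assert np.array_equal(l1, l2)

    def test_different_seed_differs(self, ape_tree):
        base = dict(tree=ape_tree.with_foreground("human"), n_codons=60)
        a1, _ = simulate_codon_alignment(SimulationSpec(seed=1, **base))
        a2, _ = simulate_codon_alignment(SimulationSpec(seed=2, **base))
        assert not np.array_equal(a1.codes, a2.codes)

    def test_p0_one_gives_all_class0_and_counting_dnds(self):
        # two-taxon tree; NG86 counting estimate is the independent oracle
        pytest.importorskip("Bio.codonalign")
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

        tree = LabeledTree(taxa=("a", "b"), parent=(2, 2, -1),
                           lengths=(0.15, 0.15, 0.0),
                           branch_names={"a": 0, "b": 1})
        spec = SimulationSpec(tree=tree, n_codons=3000, p0=1.0, p1=0.0,
                              omega0=0.2, seed=5)
        aln, labels = simulate_codon_alignment(spec)
        assert set(labels) == {"0"}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dn, ds = cal_dn_ds(CodonSeq(aln.codon_string("a")),
                               CodonSeq(aln.codon_string("b")),
                               method="NG86")
        assert dn / ds == pytest.approx(0.2, abs=0.07)

    def test_class_proportions_converge(self, ape_tree):
        spec = SimulationSpec(tree=ape_tree.with_foreground("human"),
                              n_codons=8000, seed=11)
        _, labels = simulate_codon_alignment(spec)
        expected = spec.class_proportions
        for lab, p in zip(("0", "1", "2a", "2b"), expected):
            frac = np.mean(labels == lab)
            se = np.sqrt(p * (1 - p) / 8000)
            assert abs(frac - p) <= 3 * se

    def test_invalid_proportions_rejected(self, ape_tree):
        with pytest.raises(ValueError):
            SimulationSpec(tree=ape_tree, p0=0.7, p1=0.5)
        with pytest.raises(ValueError):
            SimulationSpec(tree=ape_tree, omega0=1.5)
        with pytest.raises(ValueError):
            SimulationSpec(tree=ape_tree, omega2=0.5)


class TestInjectGaps:
    def _aln(self, ape_tree):
        spec = SimulationSpec(tree=ape_tree.with_foreground("human"),
                              n_codons=30, seed=2)
        return simulate_codon_alignment(spec)[0]

    def test_empty_spec_is_identity(self, ape_tree):
        aln = self._aln(ape_tree)
        out = inject_gaps(aln, [])
        assert np.array_equal(out.codes, aln.codes)

    def test_single_gap_cell(self, ape_tree):
        aln = self._aln(ape_tree)
        out = inject_gaps(aln, [("gorilla", 13, 1)])
        assert (out.codes == GAP_CODE).sum() == 1
        assert out.codes[aln.taxa.index("gorilla"), 12] == GAP_CODE

    def test_overlapping_runs_union(self, ape_tree):
        aln = self._aln(ape_tree)
        out = inject_gaps(aln, [("human", 5, 4), ("human", 7, 4)])
        gapped = np.where(out.gap_mask[aln.taxa.index("human")])[0] + 1
        assert gapped.tolist() == [5, 6, 7, 8, 9, 10]

    def test_out_of_range_rejected(self, ape_tree):
        aln = self._aln(ape_tree)
        with pytest.raises(IndexError):
            inject_gaps(aln, [("human", 29, 5)])


class TestColumnScores:
    def test_fraction_zero_all_ones(self, ape_tree):
        aln = simulate_codon_alignment(SimulationSpec(
            tree=ape_tree.with_foreground("human"), n_codons=50, seed=3))[0]
        scores = simulate_column_scores(aln, 0.0, seed=1)
        assert (scores.score == 1.0).all()

    def test_fraction_one_all_low(self, ape_tree):
        aln = simulate_codon_alignment(SimulationSpec(
            tree=ape_tree.with_foreground("human"), n_codons=50, seed=3))[0]
        scores = simulate_column_scores(aln, 1.0, seed=1)
        assert (scores.score < 1.0).all()

    def test_low_count_within_binomial_bounds(self, ape_tree):
        from scipy.stats import binom

        aln = simulate_codon_alignment(SimulationSpec(
            tree=ape_tree.with_foreground("human"), n_codons=100, seed=3))[0]
        scores = simulate_column_scores(aln, 0.2, seed=9)
        n_low = int((scores.score < 1.0).sum())
        lo, hi = binom.ppf([0.005, 0.995], 100, 0.2)
        assert lo <= n_low <= hi


class TestVariants:
    MODEL = GeneModel("g1", "chr1", "+", ((1001, 1090),))

    def test_zero_variant_mode_possible_for_fixed(self):
        records = simulate_variants(self.MODEL, sites=[1, 2, 3, 4],
                                    fixed_flags=[True] * 4, seed=1,
                                    af_available=False)
        assert records == []  # no-AF mode: fixed sites carry no variant

    def test_not_fixed_site_has_record_in_span(self):
        records = simulate_variants(self.MODEL, sites=[5],
                                    fixed_flags=[False], seed=2)
        span = self.MODEL.codon_span(5)
        assert any(r.pos in span.positions for r in records)

    @pytest.mark.parametrize("af_available", [True, False])
    def test_round_trip_against_fixation_caller(self, af_available):
        sites = list(range(1, 21))
        rng = np.random.default_rng(4)
        flags = [bool(b) for b in rng.integers(0, 2, size=len(sites))]
        records = simulate_variants(self.MODEL, sites, flags, seed=3,
                                    af_available=af_available, n_noise=5)
        variants = [VariantRecord(r.chrom, r.pos, r.ref, (r.alt,),
                                  (r.alt_af,) if r.alt_af is not None else None)
                    for r in records]
        for site, flag in zip(sites, flags):
            call = is_site_fixed(self.MODEL.codon_span(site), variants,
                                 af_available=af_available)
            assert call.fixed == flag, f"site {site}"

    def test_site_outside_cds_rejected(self):
        with pytest.raises(IndexError):
            simulate_variants(self.MODEL, sites=[31], fixed_flags=[True],
                              seed=1)


class TestExpression:
    def test_matrix_shape(self):
        genes = [f"g{i}" for i in range(10)]
        mat = simulate_expression(genes, n_tissues=13, seed=1)
        assert mat.shape == (10, 13)
        assert (mat.to_numpy() >= 0).all()

    def test_specific_genes_have_high_tau(self):
        mat = simulate_expression(["g1"], specific_fraction=1.0, seed=2)
        log = np.log2(mat.to_numpy()[0] + 1)
        assert tau(log) > 0.8

    def test_uniform_genes_have_low_tau(self):
        mat = simulate_expression(["g1"], specific_fraction=0.0, seed=2)
        log = np.log2(mat.to_numpy()[0] + 1)
        assert tau(log) < 0.2

    def test_too_few_tissues_rejected(self):
        with pytest.raises(ValueError):
            simulate_expression(["g1"], n_tissues=1, seed=1)


class TestRelaxSimulation:
    def test_foreground_neutralised_at_small_k(self, ape_tree):
        aln, classes = simulate_relax_alignment(
            ape_tree.with_foreground("human"), k=0.3, n_codons=100, seed=5)
        assert aln.codes.shape == (6, 100)
        assert set(classes) <= {0, 1, 2}

    def test_k_must_be_positive(self, ape_tree):
        with pytest.raises(ValueError):
            simulate_relax_alignment(ape_tree.with_foreground("human"), k=0.0)


class TestOrthologSet:
    def test_psg_count_rounding(self):
        assert n_psg_genes(20, 0.25) == 5
        assert n_psg_genes(10, 0.25) == 3   # 2.5 rounds up
        assert n_psg_genes(10, 0.0) == 0
        assert n_psg_genes(10, 1.0) == 10

    def test_dataset_cross_references(self, tmp_path):
        ds = simulate_ortholog_set(n_genes=8, psg_fraction=0.25,
                                   n_codons=40, seed=6)
        assert ds.truth.is_psg.sum() == 2
        # every gene appears exactly once in the family map
        assert sorted(ds.family_map.gene_id) == ds.genes
        assert ds.family_map.gene_id.is_unique
        # truth covers every gene; all tables keyed consistently
        assert sorted(ds.truth.gene_id) == ds.genes
        assert sorted(ds.expression.index) == ds.genes
        for gene in ds.genes:
            assert set(ds.cds[gene]) == set(ds.tree.taxa)
            assert gene in ds.alignments

        manifest = write_dataset(ds, tmp_path)
        assert manifest.exists()
        assert (tmp_path / "species_tree.nwk").exists()
        assert (tmp_path / "variants" / "human.vcf").exists()
        truth = pd.read_csv(tmp_path / "truth.tsv", sep="\t")
        assert len(truth) == 8

    def test_dataset_determinism(self):
        d1 = simulate_ortholog_set(n_genes=5, n_codons=30, seed=9)
        d2 = simulate_ortholog_set(n_genes=5, n_codons=30, seed=9)
        assert d1.truth.equals(d2.truth)
        for g in d1.genes:
            assert np.array_equal(d1.alignments[g].codes,
                                  d2.alignments[g].codes)
        assert d1.expression.equals(d2.expression)

    def test_psg_genes_marked_with_omega2(self):
        ds = simulate_ortholog_set(n_genes=6, psg_fraction=0.5, n_codons=30,
                                   seed=2)
        assert set(ds.truth[ds.truth.is_psg].omega2) == {8.0}
        assert set(ds.truth[~ds.truth.is_psg].omega2) == {1.0}
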