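"""Back-translation, coordinate mapping and column scores."""

import numpy as np
import pandas as pd
import pytest

from apescan.alignment import (
    CodonAlignment,
    GeneModel,
    attach_column_scores,
    backtranslate,
    gene_models_from_gff3,
    map_site,
)
from apescan.qc import translate_cds
from apescan.simulate import SimulationSpec, simulate_codon_alignment


class TestBacktranslate:
    def test_gap_becomes_gap_codon(self):
        aln = backtranslate({"t1": "M-K", "t2": "MQK"},
                            {"t1": "ATGAAA", "t2": "ATGCAAAAA"})
        assert aln.codon_string("t1") == "ATG---AAA"
        assert aln.codon_string("t2") == "ATGCAAAAA"

    def test_gapless_is_concatenation_of_codons(self):
        cds = "ATGCAAAAATTT"
        aln = backtranslate({"t1": "MQKF"}, {"t1": cds})
        assert aln.codon_string("t1") == cds

    def test_round_trip_on_simulated_alignment(self, ape_tree):
        spec = SimulationSpec(tree=ape_tree.with_foreground("human"),
                              n_codons=40, seed=3)
        sim, _ = simulate_codon_alignment(spec)
        prot = {t: translate_cds(sim.codon_string(t)) for t in sim.taxa}
        cds = {t: sim.ungapped_cds(t) for t in sim.taxa}
        back = backtranslate(prot, cds)
        assert np.array_equal(back.codes, sim.codes)

    def test_mismatch_names_taxon_and_position(self):
        with pytest.raises(ValueError, match="t1.*position 2"):
            backtranslate({"t1": "MK"}, {"t1": "ATGCAA"})  # CDS says MQ


class TestMapSite:
    def test_gapless_row_first_column(self):
        aln = CodonAlignment.from_strings({"t1": "ATGAAA"})
        coord = map_site(aln, 1, "t1")
        assert coord.ungapped_position == 1

    def test_gap_shifts_ungapped_position(self):
        aln = CodonAlignment.from_strings({"t1": "ATG---AAA"})
        coord = map_site(aln, 3, "t1")
        assert coord.ungapped_position == 2

    def test_gapped_cell_yields_no_coordinate(self):
        aln = CodonAlignment.from_strings({"t1": "ATG---AAA"})
        coord = map_site(aln, 2, "t1")
        assert coord.ungapped_position is None
        assert coord.codon_span is None

    def test_forward_strand_genomic_span(self):
        # single exon starting at 101: aa position 2 -> bases 104..106
        aln = CodonAlignment.from_strings({"t1": "ATGAAATTT"})
        model = GeneModel("g", "chr1", "+", ((101, 109),))
        coord = map_site(aln, 2, "t1", model)
        assert coord.codon_span.positions == (104, 105, 106)

    def test_reverse_strand_span_ascending_with_strand_flag(self):
        aln = CodonAlignment.from_strings({"t1": "ATGAAATTT"})
        model = GeneModel("g", "chr1", "-", ((101, 109),))
        coord = map_site(aln, 1, "t1", model)
        # first codon of a - strand gene occupies the top three bases
        assert coord.codon_span.positions == (107, 108, 109)
        assert coord.codon_span.strand == "-"

    def test_intron_split_codon_lists_discontiguous_positions(self):
        # exon1 = 101..104 (4 bases), exon2 = 205..209: codon 2 spans both
        aln = CodonAlignment.from_strings({"t1": "ATGAAATTT"})
        model = GeneModel("g", "chr1", "+", ((101, 104), (205, 209)))
        coord = map_site(aln, 2, "t1", model)
        assert coord.codon_span.positions == (104, 205, 206)

    def test_coordinate_bijection_on_nongap_cells(self, selected_alignment):
        aln, _ = selected_alignment
        for taxon in aln.taxa[:2]:
            seen = {}
            for col in range(1, aln.n_columns + 1):
                pos = map_site(aln, col, taxon).ungapped_position
                if pos is not None:
                    assert pos not in seen
                    seen[pos] = col
            # positions are exactly 1..n without holes
            assert sorted(seen) == list(range(1, len(seen) + 1))

    def test_column_out_of_range(self):
        aln = CodonAlignment.from_strings({"t1": "ATGAAA"})
        with pytest.raises(IndexError):
            map_site(aln, 3, "t1")


class TestColumnScores:
    def _aln(self):
        return CodonAlignment.from_strings({"t1": "ATGAAATTT"})

    def test_attach_and_read_back(self):
        table = pd.DataFrame({"column_index": [1, 2, 3],
                              "score": [1.0, 0.8, 1.0]})
        aln = attach_column_scores(self._aln(), table)
        np.testing.assert_allclose(aln.column_scores, [1.0, 0.8, 1.0])

    def test_out_of_range_score_rejected(self):
        table = pd.DataFrame({"column_index": [1, 2, 3],
                              "score": [1.0, 1.2, 1.0]})
        with pytest.raises(ValueError):
            attach_column_scores(self._aln(), table)

    def test_missing_column_rejected(self):
        table = pd.DataFrame({"column_index": [1, 3], "score": [1.0, 1.0]})
        with pytest.raises(ValueError):
            attach_column_scores(self._aln(), table)

    def test_duplicate_column_rejected(self):
        table = pd.DataFrame({"column_index": [1, 2, 2],
                              "score": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError):
            attach_column_scores(self._aln(), table)


class TestGff3RoundTrip:
    def test_written_models_read_back(self, tmp_path):
        gff = tmp_path / "test.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tx\tCDS\t101\t104\t.\t+\t0\tID=cds_g1;Parent=g1\n"
            "chr1\tx\tCDS\t205\t209\t.\t+\t0\tID=cds_g1;Parent=g1\n"
            "chr2\tx\tCDS\t50\t58\t.\t-\t0\tID=cds_g2;Parent=g2\n"
        )
        models = gene_models_from_gff3(gff)
        assert models["g1"].cds_segments == ((101, 104), (205, 209))
        assert models["g2"].strand == "-"
        assert models["g2"].codon_span(1).positions == (56, 57, 58)


class TestFastaRoundTrip:
    def test_alignment_survives_fasta(self, tmp_path, selected_alignment):
        aln, _ = selected_alignment
        path = tmp_path / "aln.fasta"
        aln.to_fasta(path)
        back = CodonAlignment.from_fasta(path)
        assert back.taxa == aln.taxa
        assert np.array_equal(back.codes, aln.codes)
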