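"""PSG filter cascade: per-stage rules and planted-design survivor counts."""

import numpy as np
import pandas as pd
import pytest

from apescan.alignment import CodonAlignment, attach_column_scores
from apescan.filters import (
    FilterConfig,
    candidate_from_fit,
    column_score_filter,
    gap_proximity_filter,
    relaxation_filter,
    run_cascade,
    records_to_frame,
)
from apescan.fit import FitComparison, RelaxFit
from apescan.simulate import SimulationSpec, inject_gaps, simulate_codon_alignment


def _comparison(p):
    return FitComparison(loglik_alt=-10.0, loglik_null=-12.0,
                         statistic=4.0, df=1, pvalue=p)


def _relax(k, p, converged=True):
    return RelaxFit(k=k, loglik_alt=-5, loglik_null=-6, pvalue=p,
                    converged=converged)


def _plain_alignment(n_cols=40, scores=None):
    seq = "ATG" * n_cols
    aln = CodonAlignment.from_strings({t: seq for t in "abc"})
    table = pd.DataFrame({
        "column_index": np.arange(1, n_cols + 1),
        "score": scores if scores is not None else np.ones(n_cols),
    })
    return attach_column_scores(aln, table)


class TestCandidate:
    def test_significant_with_sites(self):
        assert candidate_from_fit(_comparison(0.01), (3, 7))

    def test_significant_without_sites_is_not_candidate(self):
        assert not candidate_from_fit(_comparison(0.01), ())

    def test_boundary_p_excluded(self):
        assert not candidate_from_fit(_comparison(0.05), (3,))

    def test_unconverged_never_candidate(self):
        assert not candidate_from_fit(_comparison(0.001), (3,),
                                      converged=False)


class TestGapFilter:
    def _gapped(self, col):
        aln = _plain_alignment()
        return inject_gaps(aln, [("b", col, 1)])

    def test_gap_within_window_fails(self):
        passed, offending = gap_proximity_filter((10,), self._gapped(13))
        assert not passed and offending == (10,)

    def test_gap_outside_window_passes(self):
        passed, offending = gap_proximity_filter((10,), self._gapped(16))
        assert passed and offending == ()

    def test_distance_exactly_window_fails(self):
        passed, _ = gap_proximity_filter((10,), self._gapped(15))
        assert not passed

    def test_gap_at_site_column_counts(self):
        passed, _ = gap_proximity_filter((10,), self._gapped(10))
        assert not passed

    def test_mode_all_keeps_gene_with_one_clean_site(self):
        aln = self._gapped(13)
        passed_any, _ = gap_proximity_filter((10, 30), aln, mode="any")
        passed_all, _ = gap_proximity_filter((10, 30), aln, mode="all")
        assert not passed_any and passed_all

    def test_gap_in_any_taxon_counts(self):
        aln = inject_gaps(_plain_alignment(), [("c", 12, 1)])
        passed, _ = gap_proximity_filter((10,), aln)
        assert not passed


class TestColumnScoreFilter:
    def test_all_max_scores_pass(self):
        aln = _plain_alignment()
        assert column_score_filter((5, 9), aln)[0]

    def test_sub_max_score_fails(self):
        scores = np.ones(40)
        scores[8] = 0.98
        aln = _plain_alignment(scores=scores)
        passed, offending = column_score_filter((9,), aln)
        assert not passed and offending == (9,)

    def test_threshold_override(self):
        scores = np.ones(40)
        scores[8] = 0.98
        aln = _plain_alignment(scores=scores)
        assert column_score_filter((9,), aln, threshold=0.9)[0]

    def test_missing_scores_is_error(self):
        aln = CodonAlignment.from_strings({"a": "ATGATG"})
        with pytest.raises(ValueError):
            column_score_filter((1,), aln)


class TestRelaxationFilter:
    @pytest.mark.parametrize("k,p,expected", [
        (0.5, 0.01, False),   # relaxed and significant -> fail
        (0.5, 0.2, True),     # not significant -> keep
        (1.3, 0.001, True),   # intensified -> keep
    ])
    def test_rule(self, k, p, expected):
        assert relaxation_filter(_relax(k, p)) is expected

    def test_unconverged_passes_with_warning(self, caplog):
        assert relaxation_filter(_relax(0.2, 0.001, converged=False))

    def test_missing_fit_passes(self):
        assert relaxation_filter(None)


class TestCascade:
    def _planted(self):
        """Five genes engineered to drop at a known stage each."""
        alignments = {}
        tests = {}
        relax = {}
        base_scores = np.ones(40)

        # g_pass: survives everything
        alignments["g_pass"] = _plain_alignment()
        tests[("g_pass", "human")] = {"pvalue": 0.001,
                                      "selected_sites": (20,)}
        relax[("g_pass", "human")] = _relax(1.5, 0.2)
        # g_nocand: not significant
        alignments["g_nocand"] = _plain_alignment()
        tests[("g_nocand", "human")] = {"pvalue": 0.5,
                                        "selected_sites": (20,)}
        # g_gap: gap next to its selected site
        alignments["g_gap"] = inject_gaps(_plain_alignment(),
                                          [("a", 22, 1)])
        tests[("g_gap", "human")] = {"pvalue": 0.001,
                                     "selected_sites": (20,)}
        # g_score: low column score at its site
        scores = base_scores.copy()
        scores[19] = 0.7
        alignments["g_score"] = _plain_alignment(scores=scores)
        tests[("g_score", "human")] = {"pvalue": 0.001,
                                       "selected_sites": (20,)}
        relax[("g_score", "human")] = _relax(1.5, 0.2)
        # g_drift: fails the relaxation stage
        alignments["g_drift"] = _plain_alignment()
        tests[("g_drift", "human")] = {"pvalue": 0.001,
                                       "selected_sites": (20,)}
        relax[("g_drift", "human")] = _relax(0.4, 0.01)
        return tests, alignments, relax

    def test_planted_survivor_counts(self):
        tests, alignments, relax = self._planted()
        records, counts = run_cascade(tests, alignments, relax_fits=relax)
        row = counts[counts.branch == "human"].iloc[0]
        assert row.n_candidates == 4
        assert row.n_after_gap_filter == 3
        assert row.n_after_column_filter == 2
        assert row.n_after_relax_filter == 1
        frame = records_to_frame(records)
        assert frame[frame.final_psg].gene_id.tolist() == ["g_pass"]

    def test_counts_non_increasing(self):
        tests, alignments, relax = self._planted()
        _, counts = run_cascade(tests, alignments, relax_fits=relax)
        values = counts.iloc[0][list(counts.columns[1:])].to_numpy()
        assert (np.diff(values.astype(int)) <= 0).all()

    def test_order_independence(self):
        tests, alignments, relax = self._planted()
        shuffled = dict(reversed(list(tests.items())))
        f1 = records_to_frame(run_cascade(tests, alignments,
                                          relax_fits=relax)[0])
        f2 = records_to_frame(run_cascade(shuffled, alignments,
                                          relax_fits=relax)[0])
        assert f1.equals(f2)

    def test_rerun_is_idempotent(self):
        tests, alignments, relax = self._planted()
        r1, c1 = run_cascade(tests, alignments, relax_fits=relax)
        r2, c2 = run_cascade(tests, alignments, relax_fits=relax)
        assert records_to_frame(r1).equals(records_to_frame(r2))
        assert c1.equals(c2)

    def test_no_candidates_all_zero(self):
        alignments = {"g": _plain_alignment()}
        tests = {("g", "human"): {"pvalue": 0.9, "selected_sites": ()}}
        _, counts = run_cascade(tests, alignments)
        assert counts.iloc[0][list(counts.columns[1:])].sum() == 0

    def test_disabled_filters_final_equals_candidates(self):
        tests, alignments, relax = self._planted()
        config = FilterConfig(enable_gap_filter=False,
                              enable_column_filter=False,
                              enable_relax_filter=False)
        records, counts = run_cascade(tests, alignments, config=config)
        frame = records_to_frame(records)
        assert (frame.final_psg == frame.candidate).all()

    def test_gene_may_be_psg_on_multiple_branches(self):
        alignments = {"g": _plain_alignment()}
        tests = {
            ("g", "human"): {"pvalue": 0.01, "selected_sites": (5,)},
            ("g", "gorilla"): {"pvalue": 0.01, "selected_sites": (7,)},
        }
        relax = {("g", "human"): _relax(1.2, 0.5),
                 ("g", "gorilla"): _relax(1.2, 0.5)}
        records, _ = run_cascade(tests, alignments, relax_fits=relax)
        frame = records_to_frame(records)
        assert frame.final_psg.sum() == 2

    def test_key_mismatch_raises(self):
        tests = {("missing", "human"): {"pvalue": 0.01,
                                        "selected_sites": (1,)}}
        with pytest.raises(KeyError):
            run_cascade(tests, {})
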