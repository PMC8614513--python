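"""Four-stage false-positive filter cascade for PSG determination.

A gene×branch test enters the cascade as a *candidate* when its LRT
p-value is below α and it has at least one selected site (BEB posterior
above the threshold).  Candidates then pass, in order:

1. the gap-proximity filter — no alignment gap (any taxon) within 5
   amino-acid columns of a selected site;
2. the column-score filter — every selected site's alignment column
   score must reach the maximum confidence (score 1.0);
3. the relaxation filter — genes whose selection-intensity test shows
   significant relaxation (K < 1 and p < 0.05) are removed as likely
   genetic drift.

A gene is a final PSG on a branch iff it survives all stages.  All
thresholds use strict inequalities and are configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import CodonAlignment
from .fit import FitComparison, RelaxFit

logger = logging.getLogger(__name__)

STAGE_COLUMNS = (
    "n_candidates",
    "n_after_gap_filter",
    "n_after_column_filter",
    "n_after_relax_filter",
)


@dataclass
class FilterConfig:
    alpha: float = 0.05
    beb_threshold: float = 0.95
    gap_window: int = 5
    gap_mode: str = "any"          # "any": one offending site fails the gene
    column_score_threshold: float = 1.0
    relax_k_threshold: float = 1.0
    relax_alpha: float = 0.05
    enable_gap_filter: bool = True
    enable_column_filter: bool = True
    enable_relax_filter: bool = True


@dataclass
class PSGRecord:
    """Per gene × branch verdicts of the cascade."""

    gene_id: str
    branch: str
    pvalue: float
    selected_sites: tuple[int, ...]      # 1-based alignment aa columns
    converged: bool = True
    candidate: bool = False
    passed_gap_filter: bool | None = None
    passed_column_filter: bool | None = None
    passed_relax_filter: bool | None = None
    relax_k: float | None = None
    relax_p: float | None = None
    offending_gap_sites: tuple[int, ...] = ()
    offending_score_sites: tuple[int, ...] = ()

    @property
    def final_psg(self) -> bool:
        return bool(
            self.candidate
            and self.passed_gap_filter
            and self.passed_column_filter
            and self.passed_relax_filter
        )


def candidate_from_fit(
    comparison: FitComparison,
    selected_sites: tuple[int, ...],
    alpha: float = 0.05,
    converged: bool = True,
) -> bool:
    """Candidate iff p < α (strict) and at least one selected site."""
    if not converged:
        logger.warning("unconverged fit treated as non-candidate")
        return False
    return comparison.pvalue < alpha and len(selected_sites) > 0


def gap_proximity_filter(
    selected_sites: tuple[int, ...],
    alignment: CodonAlignment,
    window: int = 5,
    mode: str = "any",
) -> tuple[bool, tuple[int, ...]]:
    """Fail selected sites with a gap within ``window`` aa columns.

    A site at column c fails if any taxon has a gap anywhere in
    [c−window, c+window] (inclusive; the site's own column counts).
    ``mode="any"``: the gene fails if any selected site fails (default);
    ``mode="all"``: the gene fails only if every selected site fails.
    Returns (gene passes, offending sites).
    """
    if mode not in ("any", "all"):
        raise ValueError(f"unknown gap filter mode {mode!r}")
    gap_columns = np.where(alignment.gap_mask.any(axis=0))[0] + 1
    offending = tuple(
        site
        for site in selected_sites
        if gap_columns.size
        and np.any(np.abs(gap_columns - site) <= window)
    )
    if not selected_sites:
        return True, ()
    if mode == "any":
        passed = len(offending) == 0
    else:
        passed = len(offending) < len(selected_sites)
    return passed, offending


def column_score_filter(
    selected_sites: tuple[int, ...],
    alignment: CodonAlignment,
    threshold: float = 1.0,
) -> tuple[bool, tuple[int, ...]]:
    """Fail the gene if any selected site's column score is < threshold."""
    if alignment.column_scores is None:
        raise ValueError("alignment has no column scores attached")
    offending = tuple(
        site for site in selected_sites
        if alignment.column_scores[site - 1] < threshold
    )
    return len(offending) == 0, offending


def relaxation_filter(
    relax_fit: RelaxFit | None,
    k_threshold: float = 1.0,
    alpha: float = 0.05,
) -> bool:
    """Fail iff the relaxation test gives K < 1 with p < α.

    An unavailable or unconverged fit passes with a warning rather than
    silently dropping the gene.
    """
    if relax_fit is None or not relax_fit.converged:
        logger.warning("relaxation fit unavailable/unconverged: gene kept")
        return True
    return not (relax_fit.k < k_threshold and relax_fit.pvalue < alpha)


def run_cascade(
    tests: dict[tuple[str, str], dict],
    alignments: dict[str, CodonAlignment],
    config: FilterConfig | None = None,
    relax_fits: dict[tuple[str, str], RelaxFit] | None = None,
    relax_provider=None,
) -> tuple[list[PSGRecord], pd.DataFrame]:
    """Apply the four stages to every gene × branch test.

    ``tests`` maps (gene_id, branch) to a dict with keys ``pvalue``,
    ``selected_sites`` and optional ``converged``.  Relaxation fits may
    be supplied up front (``relax_fits``) or computed lazily for
    survivors of the column-score stage via ``relax_provider(gene,
    branch) -> RelaxFit``.  Returns the per-test records and a
    stage-count table (one row per branch, counts non-increasing).
    """
    config = config or FilterConfig()
    relax_fits = dict(relax_fits or {})
    records: list[PSGRecord] = []
    for (gene, branch), test in sorted(tests.items()):
        if gene not in alignments:
            raise KeyError(f"no alignment for gene {gene!r}")
        comparison = test.get("comparison")
        pvalue = comparison.pvalue if comparison is not None else test["pvalue"]
        sites = tuple(test["selected_sites"])
        converged = bool(test.get("converged", True))
        rec = PSGRecord(gene_id=gene, branch=branch, pvalue=pvalue,
                        selected_sites=sites, converged=converged)
        rec.candidate = (converged and pvalue < config.alpha and len(sites) > 0)
        if not rec.candidate:
            records.append(rec)
            continue
        aln = alignments[gene]
        if config.enable_gap_filter:
            rec.passed_gap_filter, rec.offending_gap_sites = (
                gap_proximity_filter(sites, aln, config.gap_window,
                                     config.gap_mode))
        else:
            rec.passed_gap_filter = True
        if not rec.passed_gap_filter:
            records.append(rec)
            continue
        if config.enable_column_filter:
            rec.passed_column_filter, rec.offending_score_sites = (
                column_score_filter(sites, aln,
                                    config.column_score_threshold))
        else:
            rec.passed_column_filter = True
        if not rec.passed_column_filter:
            records.append(rec)
            continue
        if config.enable_relax_filter:
            fit = relax_fits.get((gene, branch))
            if fit is None and relax_provider is not None:
                fit = relax_provider(gene, branch)
                relax_fits[(gene, branch)] = fit
            rec.passed_relax_filter = relaxation_filter(
                fit, config.relax_k_threshold, config.relax_alpha)
            if fit is not None:
                rec.relax_k = fit.k
                rec.relax_p = fit.pvalue
        else:
            rec.passed_relax_filter = True
        records.append(rec)
    return records, stage_counts(records)


def stage_counts(records: list[PSGRecord]) -> pd.DataFrame:
    """Per-branch survivor counts after each cascade stage."""
    rows = {}
    for rec in records:
        row = rows.setdefault(rec.branch, dict.fromkeys(STAGE_COLUMNS, 0))
        if rec.candidate:
            row["n_candidates"] += 1
            if rec.passed_gap_filter:
                row["n_after_gap_filter"] += 1
                if rec.passed_column_filter:
                    row["n_after_column_filter"] += 1
                    if rec.passed_relax_filter:
                        row["n_after_relax_filter"] += 1
    table = pd.DataFrame.from_dict(rows, orient="index").reset_index(
        names="branch")
    return table


def records_to_frame(records: list[PSGRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        rows.append({
            "gene_id": rec.gene_id,
            "branch": rec.branch,
            "pvalue": rec.pvalue,
            "converged": rec.converged,
            "selected_sites": ",".join(map(str, rec.selected_sites)),
            "candidate": rec.candidate,
            "passed_gap_filter": rec.passed_gap_filter,
            "passed_column_filter": rec.passed_column_filter,
            "passed_relax_filter": rec.passed_relax_filter,
            "relax_k": rec.relax_k,
            "relax_p": rec.relax_p,
            "relax_model": ("relax_style"
                            if rec.relax_k is not None else None),
            "final_psg": rec.final_psg,
        })
    return pd.DataFrame(rows)
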