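"""One-sided Fisher exact enrichment tests on 2×2 tables.

Two associations are tested over the retained-ortholog gene universe:
PSG status × multigene-family membership (per branch) and PSG status ×
disease-gene status.  The p-value is the exact hypergeometric upper
tail P(X ≥ a) for the a-cell with all margins fixed — the one-sided
test for over-representation.  Reported p-values and proportions are
rounded half-up to 3 decimals (raw values are retained).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)


def round3(x: float) -> float:
    """Round half-up to 3 decimals (matches printed-table convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.001"),
                                           rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]] with semantic labels for rows/columns."""

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple[str, str] = ("row1", "row2")
    col_labels: tuple[str, str] = ("col1", "col2")

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.total < 1:
            raise ValueError("table must contain at least one observation")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class FisherResult:
    pvalue: float
    odds_ratio: float
    alternative: str = "greater"

    def __post_init__(self):
        if not 0 < self.pvalue <= 1:
            raise ValueError("p-value must lie in (0,1]")


def fisher_upper_tail(table: ContingencyTable2x2) -> FisherResult:
    """Exact one-sided (upper-tail) Fisher test on the a-cell.

    With margins fixed, the a-cell follows a hypergeometric law; the
    p-value is P(X ≥ a).  Degenerate margins (an empty row or column)
    give p = 1 with a warning.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    row1 = a + b
    col1 = a + c
    n = table.total
    if row1 == 0 or col1 == 0 or row1 == n or col1 == n:
        logger.warning("degenerate 2x2 margins; p set to 1")
        p = 1.0
    else:
        p = float(hypergeom.sf(a - 1, n, col1, row1))
    odds = (a * d) / (b * c) if b * c > 0 else float("inf")
    return FisherResult(pvalue=min(max(p, 5e-324), 1.0), odds_ratio=odds)


def multigene_association(
    psg_genes: set[str],
    family_class: dict[str, str],
    universe: list[str],
    branch: str = "",
) -> tuple[ContingencyTable2x2, FisherResult, dict]:
    """PSG × multigene-family association for one branch.

    Rows are (multigene, single-gene) families, columns (PSG, non-PSG);
    the upper-tail test asks whether PSGs are over-represented among
    multigene-family genes.  Also reports the per-row PSG proportions
    (3 decimals).
    """
    missing = [g for g in universe if g not in family_class]
    if missing:
        raise ValueError(
            f"{len(missing)} genes lack a single/multi classification "
            f"(first: {missing[0]!r})")
    a = sum(1 for g in universe if family_class[g] == "multi" and g in psg_genes)
    b = sum(1 for g in universe if family_class[g] == "multi" and g not in psg_genes)
    c = sum(1 for g in universe if family_class[g] == "single" and g in psg_genes)
    d = len(universe) - a - b - c
    table = ContingencyTable2x2(
        a=a, b=b, c=c, d=d,
        row_labels=("multigene_family", "single_gene_family"),
        col_labels=("psg", "non_psg"),
    )
    result = fisher_upper_tail(table)
    detail = {
        "branch": branch,
        "proportion_psg_multigene": round3(a / (a + b)) if a + b else None,
        "proportion_psg_single": round3(c / (c + d)) if c + d else None,
        "pvalue_3dp": round3(result.pvalue),
    }
    return table, result, detail


def disease_association(
    psg_genes: set[str],
    disease_genes: set[str],
    universe: list[str],
) -> tuple[ContingencyTable2x2, FisherResult, dict]:
    """PSG × disease-gene association over the ortholog universe.

    Rows are (PSG, non-PSG), columns (disease, non-disease); the
    upper-tail test asks whether disease genes are over-represented
    among PSGs.  Disease genes absent from the universe are counted out
    with a log note.
    """
    if not disease_genes:
        raise ValueError("disease gene list is empty")
    in_universe = disease_genes & set(universe)
    dropped = len(disease_genes) - len(in_universe)
    if dropped:
        logger.info("%d disease genes outside the ortholog universe", dropped)
    a = len(psg_genes & in_universe)
    b = len(psg_genes - in_universe)
    c = len(in_universe - psg_genes)
    d = len(universe) - a - b - c
    table = ContingencyTable2x2(
        a=a, b=b, c=c, d=d,
        row_labels=("psg", "non_psg"),
        col_labels=("disease", "non_disease"),
    )
    result = fisher_upper_tail(table)
    detail = {
        "proportion_disease_psg": round3(a / (a + b)) if a + b else None,
        "proportion_disease_non_psg": round3(c / (c + d)) if c + d else None,
        "pvalue_3dp": round3(result.pvalue),
    }
    return table, result, detail
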