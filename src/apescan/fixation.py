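"""Population fixation of positively selected sites.

A positively selected amino-acid site is *fixed* in a population when
its codon carries no segregating alternative allele — or, when per-allele
frequencies are available, when the allele of the analysis assembly
(the VCF reference allele) exceeds frequency 0.95 at every variant
overlapping the codon.  A PSG is fixed if at least one of its selected
sites is fixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from .alignment import CodonSpan

logger = logging.getLogger(__name__)

AF_THRESHOLD = 0.95


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int                       # 1-based
    ref: str
    alts: tuple[str, ...]
    alt_afs: tuple[float, ...] | None  # aligned with alts; None if absent

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError("position must be >= 1")
        if self.alt_afs is not None:
            if len(self.alt_afs) != len(self.alts):
                raise ValueError("alt_afs must align with alts")
            if any(not 0 <= f <= 1 for f in self.alt_afs):
                raise ValueError("allele frequencies must lie in [0,1]")

    @property
    def has_alternative(self) -> bool:
        return any(a not in (".", "", "<NON_REF>") for a in self.alts)

    @property
    def reference_af(self) -> float | None:
        if self.alt_afs is None:
            return None
        return max(0.0, 1.0 - sum(self.alt_afs))


@dataclass(frozen=True)
class FixationCall:
    gene_id: str
    branch: str
    aa_column: int                  # alignment column the site came from
    codon_span: CodonSpan | None
    fixed: bool
    mode: str                       # AF_rule | no_alt_rule | no_overlap

    def __post_init__(self):
        if self.mode not in ("AF_rule", "no_alt_rule", "no_overlap"):
            raise ValueError(f"unknown evidence mode {self.mode!r}")


def overlapping_variants(
    span: CodonSpan, variants: list[VariantRecord]
) -> list[VariantRecord]:
    positions = set(span.positions)
    return [v for v in variants
            if v.chrom == span.chrom and v.pos in positions]


def is_site_fixed(
    codon_span: CodonSpan,
    variants: list[VariantRecord],
    af_available: bool,
    af_threshold: float = AF_THRESHOLD,
    gene_id: str = "?",
    branch: str = "?",
    aa_column: int = 0,
) -> FixationCall:
    """Fixation call for one codon against overlapping population variants.

    With frequencies: fixed iff the assembly (reference) allele has
    frequency > ``af_threshold`` at every overlapping variant.  Without:
    fixed iff no overlapping variant carries an alternative allele.
    No overlapping variants at all → fixed (mode ``no_overlap``).
    """
    overlap = overlapping_variants(codon_span, variants)
    if not overlap:
        return FixationCall(gene_id, branch, aa_column, codon_span,
                            fixed=True, mode="no_overlap")
    if af_available:
        fixed = True
        for v in overlap:
            if v.ref in (".", "", "N"):
                logger.warning(
                    "%s: variant at %s:%d has no usable assembly allele; "
                    "treated as not fixed", gene_id, v.chrom, v.pos)
                fixed = False
                break
            ref_af = v.reference_af
            if ref_af is None or ref_af <= af_threshold:
                fixed = False
                break
        return FixationCall(gene_id, branch, aa_column, codon_span,
                            fixed=fixed, mode="AF_rule")
    fixed = not any(v.has_alternative for v in overlap)
    return FixationCall(gene_id, branch, aa_column, codon_span,
                        fixed=fixed, mode="no_alt_rule")


def classify_gene_fixed(calls: list[FixationCall]) -> tuple[bool, int, int]:
    """Gene fixed iff ≥ 1 site fixed; returns (fixed, n_sites, n_fixed)."""
    if not calls:
        raise ValueError("gene has no selected-site fixation calls")
    n_fixed = sum(c.fixed for c in calls)
    return n_fixed >= 1, len(calls), n_fixed


# ---------------------------------------------------------------------------
# VCF IO
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Read variants (with AF INFO field when present) from a VCF file."""
    from cyvcf2 import VCF

    records: list[VariantRecord] = []
    for v in VCF(str(path)):
        af = v.INFO.get("AF")
        if af is None:
            alt_afs = None
        elif isinstance(af, (tuple, list)):
            alt_afs = tuple(float(x) for x in af)
        else:
            alt_afs = (float(af),)
        records.append(VariantRecord(
            chrom=v.CHROM, pos=v.POS, ref=v.REF,
            alts=tuple(v.ALT) if v.ALT else (".",),
            alt_afs=alt_afs,
        ))
    return records
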