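"""Ortholog-group quality control and gene-family classification.

One-to-one ortholog groups (one gene per species) are screened for
translatable gene models: a CDS is rejected if its length is not a
multiple of three or if it contains an internal in-frame stop codon.
A single terminal stop codon is trimmed rather than rejected (annotation
conventions differ on whether the stop is included).  Groups with any
failing member are excluded from the scan.

Gene families come from an external clustering and are consumed as a
membership table; a family is *multigene* if any species contributes two
or more members, otherwise *single*.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio.Seq import Seq

from .codonmodel import STOP_CODONS

_VALID = set("ACGTN")


@dataclass(frozen=True)
class CdsVerdict:
    valid: bool
    reason: str | None            # None when valid
    sequence: str                 # trimmed sequence when valid, input otherwise


@dataclass(frozen=True)
class OrthologGroup:
    """One-to-one ortholog group: exactly one gene per taxon."""

    group_id: str
    members: dict[str, tuple[str, str]]  # taxon -> (gene_id, CDS)

    def gene_id(self, taxon: str) -> str:
        return self.members[taxon][0]

    def cds(self, taxon: str) -> str:
        return self.members[taxon][1]


@dataclass(frozen=True)
class GeneFamily:
    family_id: str
    members_by_taxon: dict[str, tuple[str, ...]]

    @property
    def classification(self) -> str:
        return classify_family(self.members_by_taxon)


def validate_cds(cds: str, trim_terminal_stop: bool = True) -> CdsVerdict:
    """Check a CDS for translatability.

    Invalid if the length is not a multiple of three or an in-frame stop
    codon occurs before the final codon; a single terminal stop codon is
    trimmed (configurable).  Characters outside {A,C,G,T,N} are a format
    error.
    """
    if not cds:
        raise ValueError("empty CDS")
    seq = cds.upper()
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"non-nucleotide characters in CDS: {sorted(bad)}")
    if len(seq) % 3 != 0:
        return CdsVerdict(False, "length_not_multiple_of_three", cds)
    codons = [seq[i: i + 3] for i in range(0, len(seq), 3)]
    for idx, codon in enumerate(codons):
        if codon in STOP_CODONS:
            if idx == len(codons) - 1 and trim_terminal_stop:
                return CdsVerdict(True, None, "".join(codons[:-1]))
            return CdsVerdict(False, "internal_stop_codon", cds)
    return CdsVerdict(True, None, seq)


def translate_cds(cds: str) -> str:
    """Standard-code translation; N-containing codons become X."""
    seq = cds.upper()
    if len(seq) % 3 != 0:
        raise ValueError("CDS length not a multiple of three")
    protein = str(Seq(seq).translate())
    if "*" in protein:
        raise ValueError("internal stop codon in CDS")
    return protein


def filter_ortholog_groups(
    groups: list[OrthologGroup], trim_terminal_stop: bool = True
) -> tuple[list[OrthologGroup], "pd.DataFrame"]:
    """Exclude groups with any invalid member; return survivors + report.

    The report has one row per excluded group with the offending taxon,
    gene and reason.  Retained groups have terminal stops trimmed.
    """
    import pandas as pd

    retained: list[OrthologGroup] = []
    rows = []
    for group in groups:
        verdicts = {
            taxon: validate_cds(cds, trim_terminal_stop)
            for taxon, (gid, cds) in group.members.items()
        }
        failures = {t: v for t, v in verdicts.items() if not v.valid}
        if failures:
            for taxon, verdict in sorted(failures.items()):
                rows.append({
                    "group_id": group.group_id,
                    "taxon": taxon,
                    "gene_id": group.gene_id(taxon),
                    "reason": verdict.reason,
                })
        else:
            retained.append(OrthologGroup(
                group_id=group.group_id,
                members={
                    t: (gid, verdicts[t].sequence)
                    for t, (gid, cds) in group.members.items()
                },
            ))
    report = pd.DataFrame(rows, columns=["group_id", "taxon", "gene_id", "reason"])
    return retained, report


def classify_family(members_by_taxon: dict[str, tuple[str, ...] | list[str]]) -> str:
    """'multi' iff any species contributes ≥ 2 members, else 'single'."""
    if not any(members_by_taxon.values()):
        raise ValueError("family has no members")
    if any(len(m) >= 2 for m in members_by_taxon.values()):
        return "multi"
    return "single"


# ---------------------------------------------------------------------------
# File IO
# ---------------------------------------------------------------------------

def read_ortholog_group_fasta(path: str | Path, group_id: str | None = None) -> OrthologGroup:
    """Read a per-group multi-FASTA with headers ``taxon|gene_id``."""
    from Bio import SeqIO

    members = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" not in rec.id:
            raise ValueError(f"header {rec.id!r} is not 'taxon|gene_id'")
        taxon, gene_id = rec.id.split("|", 1)
        if taxon in members:
            raise ValueError(f"duplicate taxon {taxon!r} in {path}")
        members[taxon] = (gene_id, str(rec.seq).upper())
    gid = group_id if group_id is not None else Path(path).stem
    return OrthologGroup(group_id=gid, members=members)


def read_family_map(path: str | Path) -> "pd.DataFrame":
    """TSV with columns gene_id, family_id."""
    import pandas as pd

    table = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "family_id"}
    if not required <= set(table.columns):
        raise ValueError(f"family map needs columns {sorted(required)}")
    return table
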