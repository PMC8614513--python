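"""Codon alignments: back-translation, coordinates, column scores.

A :class:`CodonAlignment` holds one aligned codon matrix over the 61
sense codons, encoded as integers (codon index, ``GAP_CODE`` for ``---``
columns of a sequence, ``MASK_CODE`` for N-containing codons which are
treated as missing data).  Alignment columns are amino-acid columns;
all coordinates exposed by this module are 1-based inclusive, matching
GFF3/VCF conventions and the "Met 3"-style site reports.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codonmodel import CODON_INDEX, SENSE_CODONS, STOP_CODONS

GAP_CODE = -1
MASK_CODE = -2

_VALID_NUC = set("ACGTN")


def encode_codon(codon: str) -> int:
    codon = codon.upper()
    if codon == "---":
        return GAP_CODE
    if "N" in codon:
        if not set(codon) <= _VALID_NUC:
            raise ValueError(f"invalid codon {codon!r}")
        return MASK_CODE
    idx = CODON_INDEX.get(codon)
    if idx is None:
        if codon in STOP_CODONS:
            raise ValueError(f"stop codon {codon!r} in alignment")
        raise ValueError(f"invalid codon {codon!r}")
    return idx


def decode_codon(code: int) -> str:
    if code == GAP_CODE:
        return "---"
    if code == MASK_CODE:
        return "NNN"
    return SENSE_CODONS[code]


@dataclass
class CodonAlignment:
    """Aligned codon sequences with gap mask and optional column scores."""

    taxa: tuple[str, ...]
    codes: np.ndarray  # (n_taxa, n_columns) int16
    column_scores: np.ndarray | None = None

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int16)
        if self.codes.ndim != 2 or self.codes.shape[0] != len(self.taxa):
            raise ValueError("codes must be (n_taxa, n_columns)")
        if self.column_scores is not None:
            self.column_scores = np.asarray(self.column_scores, dtype=float)
            if self.column_scores.shape != (self.n_columns,):
                raise ValueError("column_scores must cover every column")

    @classmethod
    def from_strings(cls, sequences: dict[str, str]) -> "CodonAlignment":
        taxa = tuple(sequences)
        lengths = {len(s) for s in sequences.values()}
        if len(lengths) != 1:
            raise ValueError("aligned sequences must have equal length")
        (length,) = lengths
        if length % 3 != 0:
            raise ValueError("aligned length must be a multiple of 3")
        n_cols = length // 3
        codes = np.empty((len(taxa), n_cols), dtype=np.int16)
        for i, taxon in enumerate(taxa):
            seq = sequences[taxon].upper()
            for j in range(n_cols):
                codes[i, j] = encode_codon(seq[3 * j: 3 * j + 3])
        return cls(taxa=taxa, codes=codes)

    # -- views -------------------------------------------------------------
    @property
    def n_columns(self) -> int:
        return self.codes.shape[1]

    @property
    def gap_mask(self) -> np.ndarray:
        """(n_taxa, n_columns) boolean: True where a sequence has a gap."""
        return self.codes == GAP_CODE

    def codon_string(self, taxon: str) -> str:
        row = self.codes[self.taxa.index(taxon)]
        return "".join(decode_codon(int(c)) for c in row)

    def ungapped_cds(self, taxon: str) -> str:
        row = self.codes[self.taxa.index(taxon)]
        return "".join(decode_codon(int(c)) for c in row if c != GAP_CODE)

    def column_has_gap(self, column: int) -> bool:
        """Any-taxon gap at a 1-based amino-acid column."""
        return bool(self.gap_mask[:, column - 1].any())

    # -- IO ----------------------------------------------------------------
    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(self.codon_string(t)), id=t, description="")
            for t in self.taxa
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "CodonAlignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        return cls.from_strings({r.id: str(r.seq) for r in records})


# ---------------------------------------------------------------------------
# Back-translation
# ---------------------------------------------------------------------------

def backtranslate(
    protein_alignment: dict[str, str], cds_by_taxon: dict[str, str]
) -> CodonAlignment:
    """Replace each aligned residue by its source codon, gaps by ``---``.

    Raises a consistency error (naming taxon and position) if an ungapped
    protein row does not translate from its CDS.
    """
    from .qc import translate_cds

    sequences: dict[str, str] = {}
    for taxon, prot_row in protein_alignment.items():
        if taxon not in cds_by_taxon:
            raise KeyError(f"no CDS for taxon {taxon!r}")
        cds = cds_by_taxon[taxon].upper()
        translated = translate_cds(cds)
        ungapped = prot_row.replace("-", "")
        if len(ungapped) != len(translated):
            raise ValueError(
                f"{taxon}: protein row ({len(ungapped)} aa) does not match "
                f"CDS translation ({len(translated)} aa)"
            )
        codon_row = []
        pos = 0
        for col, residue in enumerate(prot_row, start=1):
            if residue == "-":
                codon_row.append("---")
                continue
            if residue.upper() != translated[pos]:
                raise ValueError(
                    f"{taxon}: residue {residue!r} at ungapped position "
                    f"{pos + 1} (column {col}) disagrees with CDS "
                    f"translation {translated[pos]!r}"
                )
            codon_row.append(cds[3 * pos: 3 * pos + 3])
            pos += 1
        sequences[taxon] = "".join(codon_row)
    return CodonAlignment.from_strings(sequences)


# ---------------------------------------------------------------------------
# Gene models and coordinate mapping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """CDS structure of one gene on the analysis assembly.

    ``cds_segments`` are (start, end) 1-based inclusive intervals in
    transcription order (ascending for ``+`` strand, descending for ``-``).
    """

    gene_id: str
    chrom: str
    strand: str
    cds_segments: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")
        for start, end in self.cds_segments:
            if start < 1 or end < start:
                raise ValueError(f"bad CDS segment ({start}, {end})")

    @property
    def cds_length(self) -> int:
        return sum(end - start + 1 for start, end in self.cds_segments)

    def genomic_positions(self) -> list[int]:
        """Genomic position of every CDS base, in transcription order."""
        out: list[int] = []
        for start, end in self.cds_segments:
            if self.strand == "+":
                out.extend(range(start, end + 1))
            else:
                out.extend(range(end, start - 1, -1))
        return out

    def codon_span(self, aa_position: int) -> "CodonSpan":
        """Genomic positions of the three bases of a 1-based codon."""
        positions = self.genomic_positions()
        lo = (aa_position - 1) * 3
        if aa_position < 1 or lo + 3 > len(positions):
            raise IndexError(
                f"amino-acid position {aa_position} outside CDS of "
                f"{self.gene_id} ({len(positions) // 3} codons)"
            )
        triple = positions[lo: lo + 3]
        return CodonSpan(
            chrom=self.chrom,
            positions=tuple(sorted(triple)),
            strand=self.strand,
        )


@dataclass(frozen=True)
class CodonSpan:
    """The three genomic positions of one codon (ascending order)."""

    chrom: str
    positions: tuple[int, int, int]
    strand: str


@dataclass(frozen=True)
class SiteCoordinate:
    """A selected site in alignment, per-species, and genomic coordinates."""

    aa_column: int                       # 1-based alignment column
    taxon: str
    ungapped_position: int | None        # 1-based within the taxon's protein
    codon_span: CodonSpan | None = None


def map_site(
    alignment: CodonAlignment,
    aa_column: int,
    taxon: str,
    gene_model: GeneModel | None = None,
) -> SiteCoordinate:
    """Map a 1-based alignment column to per-species coordinates.

    The ungapped position is the count of non-gap residues up to and
    including the column in that taxon's row; gapped cells yield a
    "no coordinate" result rather than an exception.
    """
    if not 1 <= aa_column <= alignment.n_columns:
        raise IndexError(f"column {aa_column} outside alignment")
    row = alignment.codes[alignment.taxa.index(taxon)]
    if row[aa_column - 1] == GAP_CODE:
        return SiteCoordinate(aa_column=aa_column, taxon=taxon,
                              ungapped_position=None, codon_span=None)
    ungapped = int(np.sum(row[:aa_column] != GAP_CODE))
    span = None
    if gene_model is not None:
        span = gene_model.codon_span(ungapped)
    return SiteCoordinate(aa_column=aa_column, taxon=taxon,
                          ungapped_position=ungapped, codon_span=span)


def gene_models_from_gff3(path: str | Path) -> dict[str, GeneModel]:
    """Read CDS features from a GFF3 file into gene models."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    models: dict[str, GeneModel] = {}
    segments: dict[str, list[tuple[int, int, str, str]]] = {}
    for feat in db.features_of_type("CDS"):
        gene_id = feat.attributes.get("Parent", feat.attributes.get("ID", ["?"]))[0]
        gene_id = gene_id.removeprefix("transcript:").removesuffix(".t1")
        segments.setdefault(gene_id, []).append(
            (feat.start, feat.end, feat.seqid, feat.strand)
        )
    for gene_id, segs in segments.items():
        chrom = segs[0][2]
        strand = segs[0][3]
        ordered = sorted((s[:2] for s in segs), reverse=(strand == "-"))
        models[gene_id] = GeneModel(
            gene_id=gene_id, chrom=chrom, strand=strand,
            cds_segments=tuple(ordered),
        )
    return models


# ---------------------------------------------------------------------------
# Column confidence scores
# ---------------------------------------------------------------------------

def attach_column_scores(
    alignment: CodonAlignment, score_table
) -> CodonAlignment:
    """Attach per-column confidence scores (e.g. GUIDANCE column scores).

    ``score_table`` is a DataFrame with columns ``column_index`` (1-based)
    and ``score``, indexing every amino-acid column exactly once.
    """
    import pandas as pd

    table = pd.DataFrame(score_table)
    cols = table["column_index"].to_numpy()
    if sorted(cols.tolist()) != list(range(1, alignment.n_columns + 1)):
        raise ValueError("score table must index every column exactly once")
    scores = np.empty(alignment.n_columns)
    scores[cols - 1] = table["score"].to_numpy(dtype=float)
    if np.any(scores < 0) or np.any(scores > 1):
        raise ValueError("column scores must lie in [0, 1]")
    return replace(alignment, column_scores=scores)
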