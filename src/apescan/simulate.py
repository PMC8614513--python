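"""Synthetic-data generation for the positive-selection scan.

Generates every input the pipeline consumes — codon alignments evolved
under a branch-site process on the six-primate tree, gap patterns,
alignment column scores, population variant tables, CDS/protein FASTA,
gene models, a gene-family map, a tissue-expression matrix and a
disease-gene list — together with a truth table recording which genes
were simulated under positive selection and at which sites.

All randomness flows from one integer seed through named sub-streams
(alignment, gaps, scores, variants, expression, ...), so each stage is
individually reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import CodonAlignment, GAP_CODE, GeneModel
from .codonmodel import N_CODONS, uniform_frequencies
from .likelihood import SiteClass
from .qc import translate_cds
from .trees import FOREGROUND_BRANCHES, LabeledTree, great_ape_tree

SITE_CLASS_LABELS = ("0", "1", "2a", "2b")

#: Tissues of the synthetic expression atlas (13, mirroring a human
#: multi-tissue RNA-seq panel).
TISSUES = tuple(f"tissue_{i:02d}" for i in range(1, 14))


def substream_rng(seed: int, name: str) -> np.random.Generator:
    """Independent, reproducible generator for a named sub-stream."""
    return np.random.default_rng([int(seed) % (2**31), zlib.crc32(name.encode())])


# ---------------------------------------------------------------------------
# Simulation spec
# ---------------------------------------------------------------------------

@dataclass
class SimulationSpec:
    """Parameters of the branch-site generative process for one gene."""

    tree: LabeledTree
    n_codons: int = 300
    kappa: float = 2.0
    p0: float = 0.35
    p1: float = 0.35
    omega0: float = 0.2
    omega2: float = 8.0
    codon_freqs: np.ndarray = field(default_factory=uniform_frequencies)
    seed: int = 0

    def __post_init__(self):
        if self.n_codons < 1:
            raise ValueError("n_codons must be positive")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if not (0 <= self.p0 and 0 <= self.p1 and self.p0 + self.p1 <= 1 + 1e-12):
            raise ValueError("need p0,p1 >= 0 and p0+p1 <= 1")
        if not (0 < self.omega0 < 1):
            raise ValueError("omega0 must lie in (0,1)")
        if self.omega2 < 1:
            raise ValueError("omega2 must be >= 1")
        self.codon_freqs = np.asarray(self.codon_freqs, dtype=float)
        if self.codon_freqs.shape != (N_CODONS,):
            raise ValueError(f"codon_freqs must have shape ({N_CODONS},)")
        if np.any(self.codon_freqs < 0) or abs(self.codon_freqs.sum() - 1) > 1e-12:
            raise ValueError("codon_freqs must be nonnegative and sum to 1")

    @property
    def class_proportions(self) -> np.ndarray:
        """(p0, p1, p2a, p2b) with the branch-site constraint."""
        s = self.p0 + self.p1
        if s <= 0:
            return np.array([0.0, 0.0, 0.5, 0.5])
        q = self.p0 / s
        return np.array([self.p0, self.p1, q * (1 - s), (1 - q) * (1 - s)])

    def site_classes(self) -> list[SiteClass]:
        w = self.class_proportions
        return [
            SiteClass(w[0], self.omega0, self.omega0),
            SiteClass(w[1], 1.0, 1.0),
            SiteClass(w[2], self.omega0, self.omega2),
            SiteClass(w[3], 1.0, self.omega2),
        ]


# ---------------------------------------------------------------------------
# Codon alignment simulation
# ---------------------------------------------------------------------------

def _sample_states(p: np.ndarray, parents: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Vectorised categorical draw: child states from rows P[parent]."""
    u = rng.random(parents.shape[0])
    cum = np.cumsum(p, axis=1)
    child = (cum[parents] < u[:, None]).sum(axis=1)
    return np.minimum(child, p.shape[0] - 1)


def _simulate_with_classes(
    tree: LabeledTree,
    classes: list[SiteClass],
    kappa: float,
    codon_freqs: np.ndarray,
    n_codons: int,
    rng: np.random.Generator,
) -> tuple[CodonAlignment, np.ndarray]:
    """Evolve codons along the tree under a site-class mixture.

    Each site draws a class; the root codon comes from the equilibrium
    frequencies and evolves down every branch under the class- and
    branch-appropriate ω (neutral-scaled matrices, matching the
    likelihood engine).  Returns the alignment and per-site class index.
    """
    from .codonmodel import SpectralQ

    if tree.n_tips < 2:
        raise ValueError("tree must have at least 2 taxa")
    weights = np.array([c.weight for c in classes])
    site_class = rng.choice(len(classes), size=n_codons, p=weights)
    fg_nodes = tree.foreground_nodes()

    spectral_cache: dict[float, SpectralQ] = {}

    def spectral(omega: float) -> SpectralQ:
        if omega not in spectral_cache:
            spectral_cache[omega] = SpectralQ.from_rates(
                kappa, omega, codon_freqs, scale="neutral")
        return spectral_cache[omega]

    states = np.empty((tree.n_nodes, n_codons), dtype=np.int64)
    states[tree.root] = rng.choice(N_CODONS, size=n_codons, p=codon_freqs)
    # preorder: parents before children (node indices descend from root)
    for node in range(tree.n_nodes - 2, -1, -1):
        parent_states = states[tree.parent[node]]
        t = tree.lengths[node]
        fg = node in fg_nodes
        child = np.empty(n_codons, dtype=np.int64)
        for c, cl in enumerate(classes):
            mask = site_class == c
            if not mask.any():
                continue
            omega = cl.omega_foreground if fg else cl.omega_background
            p = spectral(omega).transition_matrix(t)
            child[mask] = _sample_states(p, parent_states[mask], rng)
        states[node] = child

    codes = states[: tree.n_tips].astype(np.int16)
    return CodonAlignment(taxa=tree.taxa, codes=codes), site_class


def simulate_codon_alignment(
    spec: SimulationSpec,
) -> tuple[CodonAlignment, np.ndarray]:
    """Evolve a codon alignment under the branch-site process.

    Each site draws a class from (p0, p1, p2a, p2b); codons start at the
    root from the equilibrium frequencies and evolve down every branch
    under the class- and branch-appropriate ω.  Returns the alignment
    (rows = tree taxa) and the per-site true class labels
    (one of ``"0" "1" "2a" "2b"``).
    """
    rng = substream_rng(spec.seed, "alignment")
    alignment, site_class = _simulate_with_classes(
        spec.tree, spec.site_classes(), spec.kappa, spec.codon_freqs,
        spec.n_codons, rng)
    labels = np.array([SITE_CLASS_LABELS[c] for c in site_class])
    return alignment, labels


def simulate_relax_alignment(
    tree: LabeledTree,
    k: float,
    n_codons: int = 300,
    kappa: float = 2.0,
    omegas: tuple[float, float, float] = (0.2, 1.0, 2.0),
    weights: tuple[float, float, float] = (0.4, 0.4, 0.2),
    codon_freqs: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[CodonAlignment, np.ndarray]:
    """Evolve codons under the selection-intensity (K) generative model.

    Three ω classes are shared by all branches; on the foreground/test
    branches each class ω is raised to the power ``k`` (K < 1 relaxes
    selection toward neutrality, K > 1 intensifies it).
    """
    if k <= 0:
        raise ValueError("K must be positive")
    if codon_freqs is None:
        codon_freqs = uniform_frequencies()
    classes = [
        SiteClass(w, om, om ** k) for w, om in zip(weights, omegas)
    ]
    rng = substream_rng(seed, "relax_alignment")
    return _simulate_with_classes(tree, classes, kappa, codon_freqs,
                                  n_codons, rng)


def inject_gaps(
    alignment: CodonAlignment,
    gap_spec: list[tuple[str, int, int]],
) -> CodonAlignment:
    """Replace amino-acid columns by gap codons in named taxa.

    ``gap_spec`` entries are (taxon, 1-based aa column, run length).
    Overlapping runs union; all other cells are untouched.
    """
    codes = alignment.codes.copy()
    for taxon, col, run in gap_spec:
        if run < 1:
            raise ValueError("run length must be >= 1")
        if not 1 <= col <= alignment.n_columns or col + run - 1 > alignment.n_columns:
            raise IndexError(f"gap run ({taxon}, {col}, {run}) outside alignment")
        row = alignment.taxa.index(taxon)
        codes[row, col - 1: col - 1 + run] = GAP_CODE
    return replace(alignment, codes=codes)


def simulate_column_scores(
    alignment: CodonAlignment, fraction_low: float, seed: int
) -> pd.DataFrame:
    """Per-column confidence scores: ≈``fraction_low`` of columns < 1.0.

    Low columns draw a score uniformly from [0.50, 0.99] (3 decimals);
    all other columns score exactly 1.0.
    """
    if not 0 <= fraction_low <= 1:
        raise ValueError("fraction_low must lie in [0,1]")
    rng = substream_rng(seed, "scores")
    n = alignment.n_columns
    low = rng.random(n) < fraction_low
    scores = np.ones(n)
    scores[low] = np.round(rng.uniform(0.50, 0.99, size=low.sum()), 3)
    return pd.DataFrame({"column_index": np.arange(1, n + 1), "score": scores})


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class SimulatedVariant:
    chrom: str
    pos: int           # 1-based
    ref: str
    alt: str
    alt_af: float | None  # None in populations without frequency data


def simulate_variants(
    gene_model: GeneModel,
    sites: list[int],
    fixed_flags: list[bool],
    seed: int,
    af_available: bool = True,
    n_noise: int = 0,
) -> list[SimulatedVariant]:
    """Population variants consistent with per-site fixation flags.

    For a *fixed* site, either no variant overlaps its codon or (AF mode
    only) the overlapping variant leaves the assembly/reference allele at
    frequency > 0.95.  For a *not-fixed* site, at least one overlapping
    variant violates the rule (alternative allele present; in AF mode
    with reference frequency ≤ 0.95).  ``n_noise`` extra variants are
    placed outside the listed codons.
    """
    if len(sites) != len(fixed_flags):
        raise ValueError("sites and fixed_flags must align")
    rng = substream_rng(seed, f"variants:{gene_model.gene_id}")
    n_codons = gene_model.cds_length // 3
    records: list[SimulatedVariant] = []
    occupied: set[int] = set()
    for aa_pos, fixed in zip(sites, fixed_flags):
        if not 1 <= aa_pos <= n_codons:
            raise IndexError(
                f"site {aa_pos} outside CDS of {gene_model.gene_id}")
        span = gene_model.codon_span(aa_pos)
        occupied.update(span.positions)
        if fixed:
            if not af_available or rng.random() < 0.5:
                continue  # zero-variant mode: invariant codon
            alt_af = float(np.round(rng.uniform(0.001, 0.04), 4))
        else:
            alt_af = (float(np.round(rng.uniform(0.10, 0.60), 4))
                      if af_available else None)
        pos = int(rng.choice(span.positions))
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        records.append(SimulatedVariant(span.chrom, pos, ref, alt, alt_af))
    cds_positions = [p for p in gene_model.genomic_positions()
                     if p not in occupied]
    for _ in range(n_noise):
        if not cds_positions:
            break
        pos = int(rng.choice(cds_positions))
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        af = float(np.round(rng.uniform(0.01, 0.9), 4)) if af_available else None
        records.append(SimulatedVariant(gene_model.chrom, pos, ref, alt, af))
    return sorted(records, key=lambda r: (r.chrom, r.pos))


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def simulate_expression(
    genes: list[str],
    n_tissues: int = len(TISSUES),
    specific_fraction: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """TPM matrix: ≈``specific_fraction`` of genes single-tissue dominant.

    Tissue-specific genes express at 200–1000 TPM in one tissue and
    below 0.5 TPM elsewhere (τ near 1 on the log scale); the remainder
    express near-uniformly (τ near 0).
    """
    if n_tissues < 2:
        raise ValueError("need at least 2 tissues")
    rng = substream_rng(seed, "expression")
    tissues = (list(TISSUES[:n_tissues])
               if n_tissues <= len(TISSUES)
               else [f"tissue_{i:02d}" for i in range(1, n_tissues + 1)])
    data = np.empty((len(genes), n_tissues))
    for i in range(len(genes)):
        if rng.random() < specific_fraction:
            row = rng.uniform(0.0, 0.5, size=n_tissues)
            row[rng.integers(n_tissues)] = rng.uniform(200.0, 1000.0)
        else:
            base = rng.uniform(20.0, 200.0)
            row = base * np.exp(rng.normal(0.0, 0.1, size=n_tissues))
        data[i] = row
    return pd.DataFrame(np.round(data, 3), index=pd.Index(genes, name="gene_id"),
                        columns=tissues)


# ---------------------------------------------------------------------------
# Full ortholog set
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """A complete, cross-referenced input set for one pipeline run."""

    tree: LabeledTree
    genes: list[str]
    alignments: dict[str, CodonAlignment]
    cds: dict[str, dict[str, str]]                 # gene -> taxon -> CDS
    protein_alignments: dict[str, dict[str, str]]  # gene -> taxon -> aa row
    column_scores: dict[str, pd.DataFrame]
    family_map: pd.DataFrame
    expression: pd.DataFrame
    disease_genes: list[str]
    gene_models: dict[str, dict[str, GeneModel]]   # taxon -> gene -> model
    variants: dict[str, list[SimulatedVariant]]    # taxon -> records
    truth: pd.DataFrame
    params: dict


#: Populations with per-allele frequencies in their variant tables.
AF_POPULATIONS = frozenset({"human"})
POPULATION_TAXA = ("human", "chimpanzee", "gorilla", "orangutan")


def _truncated_geometric(rng, p=0.45, max_size=6) -> int:
    size = 1 + rng.geometric(p) - 1  # support {1, 2, ...}
    return int(min(size, max_size))


def n_psg_genes(n_genes: int, psg_fraction: float) -> int:
    """Round psg_fraction × n_genes to the nearest integer, ties up."""
    import math

    return int(math.floor(n_genes * psg_fraction + 0.5))


def simulate_ortholog_set(
    n_genes: int = 20,
    psg_fraction: float = 0.25,
    n_codons: int = 300,
    omega2: float = 8.0,
    seed: int = 0,
    tree: LabeledTree | None = None,
    foreground_branches: tuple[str, ...] = FOREGROUND_BRANCHES,
    gap_gene_fraction: float = 0.2,
    low_score_fraction: float = 0.05,
    fixed_site_fraction: float = 0.8,
    disease_fraction: float = 0.2,
    family_geometric_p: float = 0.45,
) -> SyntheticDataset:
    """Generate a complete synthetic study input set.

    Genes flagged PSG in the truth table evolve with ω2 on a designated
    foreground branch (cycling through ``foreground_branches``); all
    other genes evolve under the null (ω2 = 1).  The number of PSGs is
    ``psg_fraction × n_genes`` rounded to the nearest integer, ties up.
    """
    if not 0 <= psg_fraction <= 1:
        raise ValueError("psg_fraction must lie in [0,1]")
    base_tree = tree if tree is not None else great_ape_tree()
    rng = substream_rng(seed, "ortholog_set")
    genes = [f"g{i:04d}" for i in range(1, n_genes + 1)]
    n_psg = n_psg_genes(n_genes, psg_fraction)
    is_psg = np.zeros(n_genes, dtype=bool)
    psg_idx = rng.choice(n_genes, size=n_psg, replace=False)
    is_psg[psg_idx] = True

    alignments: dict[str, CodonAlignment] = {}
    cds: dict[str, dict[str, str]] = {}
    proteins: dict[str, dict[str, str]] = {}
    scores: dict[str, pd.DataFrame] = {}
    truth_rows = []
    fg_cycle = 0
    for i, gene in enumerate(genes):
        gene_seed = int(substream_rng(seed, f"gene:{gene}").integers(2**31))
        if is_psg[i]:
            branch = foreground_branches[fg_cycle % len(foreground_branches)]
            fg_cycle += 1
            w2 = omega2
        else:
            branch = foreground_branches[i % len(foreground_branches)]
            w2 = 1.0
        spec = SimulationSpec(
            tree=base_tree.with_foreground(branch),
            n_codons=n_codons, omega2=w2, seed=gene_seed,
        )
        aln, labels = simulate_codon_alignment(spec)
        gap_rng = substream_rng(gene_seed, "gaps")
        if gap_rng.random() < gap_gene_fraction:
            taxon = base_tree.taxa[gap_rng.integers(base_tree.n_tips)]
            col = int(gap_rng.integers(1, n_codons + 1))
            run = int(gap_rng.integers(1, 4))
            run = min(run, n_codons - col + 1)
            aln = inject_gaps(aln, [(taxon, col, run)])
        alignments[gene] = aln
        scores[gene] = simulate_column_scores(aln, low_score_fraction, gene_seed)
        gene_cds = {}
        gene_prot = {}
        for taxon in base_tree.taxa:
            ungapped = aln.ungapped_cds(taxon)
            gene_cds[taxon] = ungapped + "TAA"
            row = []
            codons = aln.codon_string(taxon)
            for j in range(aln.n_columns):
                codon = codons[3 * j: 3 * j + 3]
                row.append("-" if codon == "---" else translate_cds(codon))
            gene_prot[taxon] = "".join(row)
        cds[gene] = gene_cds
        proteins[gene] = gene_prot
        # class-2 columns are genuinely selected only when ω2 > 1
        if w2 > 1.0:
            selected_cols = [int(c) + 1 for c in np.where(
                (labels == "2a") | (labels == "2b"))[0]]
        else:
            selected_cols = []
        site_rng = substream_rng(gene_seed, "fixation_truth")
        fixed = [bool(site_rng.random() < fixed_site_fraction)
                 for _ in selected_cols]
        truth_rows.append({
            "gene_id": gene,
            "is_psg": bool(is_psg[i]),
            "foreground_branch": branch,
            "omega2": w2,
            "true_selected_columns": ",".join(map(str, selected_cols)),
            "fixed_flags": ",".join("1" if f else "0" for f in fixed),
        })
    truth = pd.DataFrame(truth_rows)

    # family map: truncated-geometric family sizes over the gene list
    fam_rng = substream_rng(seed, "families")
    family_map_rows = []
    fam_id = 0
    i = 0
    while i < n_genes:
        size = _truncated_geometric(fam_rng, p=family_geometric_p)
        fam_id += 1
        for gene in genes[i: i + size]:
            family_map_rows.append(
                {"gene_id": gene, "family_id": f"fam{fam_id:04d}"})
        i += size
    family_map = pd.DataFrame(family_map_rows)

    expression = simulate_expression(genes, seed=seed)
    dis_rng = substream_rng(seed, "disease")
    n_disease = max(1, int(round(disease_fraction * n_genes)))
    disease_genes = sorted(
        dis_rng.choice(genes, size=n_disease, replace=False).tolist())

    # gene models laid along one synthetic chromosome per population taxon
    gene_models: dict[str, dict[str, GeneModel]] = {}
    variants: dict[str, list[SimulatedVariant]] = {}
    for taxon in POPULATION_TAXA:
        models: dict[str, GeneModel] = {}
        offset = 1000
        for k, gene in enumerate(genes):
            cds_len = len(cds[gene][taxon])
            if k % 3 == 2 and cds_len > 40:
                # two-exon model with the intron splitting a codon
                first = (cds_len // 2) - (cds_len // 2) % 3 + 1  # split mid-codon
                seg1 = (offset, offset + first - 1)
                seg2 = (offset + first + 100, offset + first + 100 + cds_len - first - 1)
                segments = (seg1, seg2)
                span = seg2[1] - offset + 1
            else:
                segments = ((offset, offset + cds_len - 1),)
                span = cds_len
            models[gene] = GeneModel(gene_id=gene, chrom="chr1", strand="+",
                                     cds_segments=segments)
            offset += span + 500
        gene_models[taxon] = models

        taxon_records: list[SimulatedVariant] = []
        for gene in genes:
            row = truth[truth.gene_id == gene].iloc[0]
            if not row.is_psg or not row.true_selected_columns:
                continue
            cols = [int(c) for c in row.true_selected_columns.split(",")]
            flags = [f == "1" for f in row.fixed_flags.split(",")]
            aln = alignments[gene]
            aa_sites, aa_flags = [], []
            taxon_row = aln.codes[aln.taxa.index(taxon)]
            for col, flag in zip(cols, flags):
                if taxon_row[col - 1] == GAP_CODE:
                    continue
                aa_sites.append(int(np.sum(taxon_row[:col] != GAP_CODE)))
                aa_flags.append(flag)
            taxon_records.extend(simulate_variants(
                models[gene], aa_sites, aa_flags,
                seed=int(substream_rng(seed, f"var:{taxon}:{gene}").integers(2**31)),
                af_available=taxon in AF_POPULATIONS,
            ))
        variants[taxon] = taxon_records

    return SyntheticDataset(
        tree=base_tree,
        genes=genes,
        alignments=alignments,
        cds=cds,
        protein_alignments=proteins,
        column_scores=scores,
        family_map=family_map,
        expression=expression,
        disease_genes=disease_genes,
        gene_models=gene_models,
        variants=variants,
        truth=truth,
        params={
            "n_genes": n_genes, "psg_fraction": psg_fraction,
            "n_codons": n_codons, "omega2": omega2, "seed": seed,
            "foreground_branches": list(foreground_branches),
            "gap_gene_fraction": gap_gene_fraction,
            "low_score_fraction": low_score_fraction,
            "fixed_site_fraction": fixed_site_fraction,
            "disease_fraction": disease_fraction,
        },
    )


# ---------------------------------------------------------------------------
# Writing a dataset to disk
# ---------------------------------------------------------------------------

def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> Path:
    """Write every dataset component and a manifest; returns the manifest path."""
    import yaml

    out = Path(outdir)
    for sub in ("cds", "proteins", "scores", "annotation", "variants"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    paths: dict[str, object] = {}

    for gene in ds.genes:
        cds_path = out / "cds" / f"{gene}.fasta"
        with open(cds_path, "w") as fh:
            for taxon, seq in ds.cds[gene].items():
                fh.write(f">{taxon}|{gene}_{taxon}\n{seq}\n")
        prot_path = out / "proteins" / f"{gene}.aln.fasta"
        with open(prot_path, "w") as fh:
            for taxon, row in ds.protein_alignments[gene].items():
                fh.write(f">{taxon}\n{row}\n")
        ds.column_scores[gene].to_csv(out / "scores" / f"{gene}.tsv",
                                      sep="\t", index=False)
    paths["cds_dir"] = "cds"
    paths["protein_alignment_dir"] = "proteins"
    paths["score_dir"] = "scores"

    tree_path = out / "species_tree.nwk"
    tree_path.write_text(ds.tree.to_newick() + "\n")
    paths["tree"] = "species_tree.nwk"

    ds.family_map.to_csv(out / "family_map.tsv", sep="\t", index=False)
    ds.expression.to_csv(out / "expression.tsv", sep="\t")
    pd.DataFrame({"gene_id": ds.disease_genes}).to_csv(
        out / "disease_genes.tsv", sep="\t", index=False)
    ds.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    paths.update(family_map="family_map.tsv", expression="expression.tsv",
                 disease_genes="disease_genes.tsv", truth="truth.tsv")

    for taxon, models in ds.gene_models.items():
        gff = out / "annotation" / f"{taxon}.gff3"
        with open(gff, "w") as fh:
            fh.write("##gff-version 3\n")
            for gene, model in models.items():
                for start, end in model.cds_segments:
                    fh.write(
                        f"{model.chrom}\tapescan\tCDS\t{start}\t{end}\t.\t"
                        f"{model.strand}\t0\tID=cds_{gene};Parent={gene}\n"
                    )
    paths["annotation_dir"] = "annotation"

    for taxon, records in ds.variants.items():
        vcf = out / "variants" / f"{taxon}.vcf"
        with open(vcf, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##INFO=<ID=AF,Number=A,Type=Float,'
                     'Description="Alternate allele frequency">\n')
            fh.write("##contig=<ID=chr1>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for rec in records:
                info = f"AF={rec.alt_af}" if rec.alt_af is not None else "."
                fh.write(f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}"
                         f"\t.\tPASS\t{info}\n")
    paths["variant_dir"] = "variants"

    manifest = out / "manifest.yaml"
    with open(manifest, "w") as fh:
        yaml.safe_dump({"paths": paths, "params": ds.params}, fh,
                       sort_keys=True)
    return manifest
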