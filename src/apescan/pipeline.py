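"""End-to-end orchestration of the positive-selection scan.

One configuration drives every stage: ortholog QC → codon alignments →
per-branch branch-site fits with BEB → the filter cascade (with lazy
relaxation fits for survivors) → population fixation calls → expression
comparison → association tests.  Each stage writes its tables under the
run directory and is skipped on resume when its outputs already exist,
so an interrupted run can be restarted without recomputation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import alignment as alnmod
from .alignment import CodonAlignment, attach_column_scores, backtranslate, map_site
from .beb import beb_site_posteriors
from .expression import (
    ExpressionMatrix,
    build_pairs,
    compare_pairs,
    log_transform,
    tau_table,
)
from .association import disease_association, multigene_association
from .filters import FilterConfig, records_to_frame, run_cascade
from .fit import branch_site_test, estimate_pi, fit_M0, fit_relax_style
from .fixation import is_site_fixed, read_vcf
from .likelihood import TreeLikelihood
from .qc import (
    classify_family,
    filter_ortholog_groups,
    read_family_map,
    read_ortholog_group_fasta,
)
from .trees import FOREGROUND_BRANCHES, GREAT_APE_TAXA, LabeledTree

logger = logging.getLogger(__name__)

STAGES = ("qc", "align", "fit", "filter", "fixation", "expression",
          "associate")

#: Populations whose variant data is checked for each foreground branch:
#: terminal branches use their own species; stem branches require fixation
#: in every descendant great-ape population.
BRANCH_POPULATIONS = {
    "human": ("human",),
    "chimpanzee": ("chimpanzee",),
    "gorilla": ("gorilla",),
    "orangutan": ("orangutan",),
    "Hominini": ("human", "chimpanzee"),
    "Homininae": ("human", "chimpanzee", "gorilla"),
    "Hominidae": ("human", "chimpanzee", "gorilla", "orangutan"),
}


@dataclass
class PipelineConfig:
    """All inputs and thresholds of one scan run."""

    dataset_dir: str
    outdir: str
    seed: int = 0
    foreground_branches: tuple[str, ...] = FOREGROUND_BRANCHES
    alpha: float = 0.05
    beb_threshold: float = 0.95
    gap_window: int = 5
    gap_mode: str = "any"
    column_score_threshold: float = 1.0
    relax_k_threshold: float = 1.0
    relax_alpha: float = 0.05
    fixation_af_threshold: float = 0.95
    frequency_model: str = "F3x4"
    null_distribution: str = "chi2"
    trim_terminal_stop: bool = True
    disease_branch: str = "human"

    def __post_init__(self):
        for name, value, lo, hi in (
            ("alpha", self.alpha, 0, 1),
            ("beb_threshold", self.beb_threshold, 0, 1),
            ("column_score_threshold", self.column_score_threshold, 0, 1),
            ("relax_alpha", self.relax_alpha, 0, 1),
            ("fixation_af_threshold", self.fixation_af_threshold, 0, 1),
        ):
            if not lo <= value <= hi:
                raise ValueError(f"{name}={value} outside [{lo},{hi}]")
        if self.gap_window < 0:
            raise ValueError("gap_window must be >= 0")
        unknown = set(self.foreground_branches) - set(FOREGROUND_BRANCHES)
        if unknown:
            raise ValueError(f"unknown foreground branches {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "foreground_branches" in raw:
            raw["foreground_branches"] = tuple(raw["foreground_branches"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["foreground_branches"] = list(self.foreground_branches)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def filter_config(self) -> FilterConfig:
        return FilterConfig(
            alpha=self.alpha,
            beb_threshold=self.beb_threshold,
            gap_window=self.gap_window,
            gap_mode=self.gap_mode,
            column_score_threshold=self.column_score_threshold,
            relax_k_threshold=self.relax_k_threshold,
            relax_alpha=self.relax_alpha,
        )


class ScanRun:
    """Stateful runner over a dataset directory (simulator layout)."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.dataset = Path(config.dataset_dir)
        self.out = Path(config.outdir)
        self.out.mkdir(parents=True, exist_ok=True)
        tree_text = (self.dataset / "species_tree.nwk").read_text()
        self.tree = LabeledTree.from_newick(tree_text)
        self._alignments: dict[str, CodonAlignment] | None = None
        self._stage_results: dict[str, pd.DataFrame] = {}
        self._engines: dict[str, TreeLikelihood] = {}
        self._m0_trees: dict[str, LabeledTree] = {}
        self._pis: dict[str, np.ndarray] = {}

    # -- helpers -----------------------------------------------------------
    def _path(self, name: str) -> Path:
        return self.out / name

    def _done(self, *names: str) -> bool:
        return all(self._path(n).exists() for n in names)

    # -- stage 1: QC -------------------------------------------------------
    def stage_qc(self, resume: bool = True) -> pd.DataFrame:
        if "qc" in self._stage_results:
            return self._stage_results["qc"]
        if resume and self._done("retained_groups.tsv", "exclusion_report.tsv"):
            self._stage_results["qc"] = pd.read_csv(
                self._path("retained_groups.tsv"), sep="\t")
            return self._stage_results["qc"]
        cds_dir = self.dataset / "cds"
        groups = [
            read_ortholog_group_fasta(p)
            for p in sorted(cds_dir.glob("*.fasta"))
        ]
        retained, report = filter_ortholog_groups(
            groups, trim_terminal_stop=self.config.trim_terminal_stop)
        retained_table = pd.DataFrame(
            {"gene_id": [g.group_id for g in retained]})
        retained_table.to_csv(self._path("retained_groups.tsv"),
                              sep="\t", index=False)
        report.to_csv(self._path("exclusion_report.tsv"), sep="\t", index=False)
        logger.info("QC: %d/%d groups retained", len(retained), len(groups))
        self._stage_results["qc"] = retained_table
        return retained_table

    # -- stage 2: codon alignments ----------------------------------------
    def stage_align(self, resume: bool = True) -> dict[str, CodonAlignment]:
        if self._alignments is not None:
            return self._alignments
        retained = self.stage_qc(resume)["gene_id"].tolist()
        aln_dir = self._path("alignments")
        aln_dir.mkdir(exist_ok=True)
        alignments: dict[str, CodonAlignment] = {}
        for gene in retained:
            out_fasta = aln_dir / f"{gene}.codon.fasta"
            scores = pd.read_csv(self.dataset / "scores" / f"{gene}.tsv",
                                 sep="\t")
            if resume and out_fasta.exists():
                aln = CodonAlignment.from_fasta(out_fasta)
            else:
                group = read_ortholog_group_fasta(
                    self.dataset / "cds" / f"{gene}.fasta")
                retained_group, _ = filter_ortholog_groups(
                    [group], trim_terminal_stop=self.config.trim_terminal_stop)
                cds_by_taxon = {
                    t: retained_group[0].cds(t) for t in group.members}
                prot = {}
                from Bio import SeqIO

                for rec in SeqIO.parse(
                        str(self.dataset / "proteins" / f"{gene}.aln.fasta"),
                        "fasta"):
                    prot[rec.id] = str(rec.seq)
                aln = backtranslate(prot, cds_by_taxon)
                aln.to_fasta(out_fasta)
            alignments[gene] = attach_column_scores(aln, scores)
        self._alignments = alignments
        return alignments

    # -- stage 3: per-branch fits + BEB -----------------------------------
    def _gene_engine(self, gene: str, aln: CodonAlignment):
        if gene not in self._engines:
            pi = estimate_pi(aln, self.config.frequency_model)
            self._pis[gene] = pi
            m0 = fit_M0(aln, self.tree, pi=pi)
            self._m0_trees[gene] = m0.tree
        return self._pis[gene], self._m0_trees[gene]

    def stage_fit(self, resume: bool = True) -> pd.DataFrame:
        if "fit" in self._stage_results:
            return self._stage_results["fit"]
        if resume and self._done("fits.tsv", "beb_sites.tsv"):
            self._stage_results["fit"] = pd.read_csv(self._path("fits.tsv"),
                                                     sep="\t")
            return self._stage_results["fit"]
        alignments = self.stage_align(resume)
        fit_rows, beb_rows = [], []
        for gene, aln in alignments.items():
            pi, m0_tree = self._gene_engine(gene, aln)
            for branch in self.config.foreground_branches:
                labeled = m0_tree.with_foreground(branch)
                engine = TreeLikelihood(aln, labeled, pi)
                alt, null, comp = branch_site_test(
                    aln, labeled, pi=pi, engine=engine,
                    null_distribution=self.config.null_distribution)
                beb = beb_site_posteriors(
                    aln, labeled, alt, pi=pi, engine=engine,
                    threshold=self.config.beb_threshold)
                fit_rows.append({
                    "gene_id": gene, "branch": branch,
                    "loglik_alt": alt.loglik, "loglik_null": null.loglik,
                    "statistic": comp.statistic, "pvalue": comp.pvalue,
                    "kappa": alt.kappa,
                    "p0": alt.params.p0, "p1": alt.params.p1,
                    "omega0": alt.params.omega0, "omega2": alt.params.omega2,
                    "converged": alt.converged and null.converged,
                    "selected_sites": ",".join(
                        map(str, beb.selected_sites)),
                })
                for col in beb.selected_sites:
                    site = map_site(aln, col, "human")
                    beb_rows.append({
                        "gene_id": gene, "branch": branch,
                        "aa_column": col,
                        "human_position": site.ungapped_position,
                        "posterior": beb.posteriors[col - 1],
                    })
        fits = pd.DataFrame(fit_rows)
        fits.to_csv(self._path("fits.tsv"), sep="\t", index=False,
                    float_format="%.12g")
        pd.DataFrame(
            beb_rows,
            columns=["gene_id", "branch", "aa_column", "human_position",
                     "posterior"],
        ).to_csv(self._path("beb_sites.tsv"), sep="\t", index=False,
                   float_format="%.12g")
        self._stage_results["fit"] = fits
        return fits

    # -- stage 4: cascade --------------------------------------------------
    def stage_filter(self, resume: bool = True) -> pd.DataFrame:
        if "filter" in self._stage_results:
            return self._stage_results["filter"]
        if resume and self._done("psg_table.tsv", "stage_counts.tsv"):
            self._stage_results["filter"] = pd.read_csv(
                self._path("psg_table.tsv"), sep="\t")
            return self._stage_results["filter"]
        fits = self.stage_fit(resume)
        alignments = self.stage_align(resume)
        tests = {}
        for row in fits.itertuples():
            sites = (tuple(int(s) for s in str(row.selected_sites).split(","))
                     if isinstance(row.selected_sites, str)
                     and row.selected_sites else ())
            tests[(row.gene_id, row.branch)] = {
                "pvalue": row.pvalue,
                "selected_sites": sites,
                "converged": bool(row.converged),
            }

        def relax_provider(gene, branch):
            aln = alignments[gene]
            pi, m0_tree = self._gene_engine(gene, aln)
            labeled = m0_tree.with_foreground(branch)
            return fit_relax_style(aln, labeled, pi=pi)

        records, counts = run_cascade(
            tests, alignments, config=self.config.filter_config(),
            relax_provider=relax_provider)
        table = records_to_frame(records)
        table.to_csv(self._path("psg_table.tsv"), sep="\t", index=False,
                     float_format="%.12g")
        counts.to_csv(self._path("stage_counts.tsv"), sep="\t", index=False)
        self._stage_results["filter"] = table
        return table

    # -- stage 5: fixation -------------------------------------------------
    def stage_fixation(self, resume: bool = True) -> pd.DataFrame:
        if "fixation" in self._stage_results:
            return self._stage_results["fixation"]
        if resume and self._done("fixation.tsv", "fixation_summary.tsv"):
            self._stage_results["fixation"] = pd.read_csv(
                self._path("fixation.tsv"), sep="\t")
            return self._stage_results["fixation"]
        psg_table = self.stage_filter(resume)
        alignments = self.stage_align(resume)
        models = {}
        variants = {}
        for taxon in GREAT_APE_TAXA[:4]:
            gff = self.dataset / "annotation" / f"{taxon}.gff3"
            vcf = self.dataset / "variants" / f"{taxon}.vcf"
            if gff.exists():
                models[taxon] = alnmod.gene_models_from_gff3(gff)
            if vcf.exists():
                variants[taxon] = read_vcf(vcf)
        call_rows, summary_rows = [], []
        finals = psg_table[psg_table.final_psg]
        for branch, branch_psgs in finals.groupby("branch"):
            populations = [
                p for p in BRANCH_POPULATIONS.get(branch, ())
                if p in models and p in variants
            ]
            n_psg = n_fixed_psg = n_sites = n_fixed_sites = 0
            for row in branch_psgs.itertuples():
                sites = [int(s) for s in str(row.selected_sites).split(",")
                         if s]
                aln = alignments[row.gene_id]
                site_calls = []
                for col in sites:
                    fixed_everywhere = True
                    modes = []
                    for pop in populations:
                        coord = map_site(aln, col, pop,
                                         models[pop].get(row.gene_id))
                        if coord.codon_span is None:
                            continue  # gapped in this population's species
                        call = is_site_fixed(
                            coord.codon_span, variants[pop],
                            af_available=any(
                                v.alt_afs is not None for v in variants[pop]),
                            af_threshold=self.config.fixation_af_threshold,
                            gene_id=row.gene_id, branch=branch,
                            aa_column=col)
                        modes.append(call.mode)
                        fixed_everywhere &= call.fixed
                    site_calls.append(fixed_everywhere)
                    call_rows.append({
                        "gene_id": row.gene_id, "branch": branch,
                        "aa_column": col, "fixed": fixed_everywhere,
                        "mode": "+".join(sorted(set(modes))) or "no_overlap",
                    })
                n_psg += 1
                n_sites += len(site_calls)
                n_fixed_sites += sum(site_calls)
                n_fixed_psg += any(site_calls)
            summary_rows.append({
                "branch": branch, "n_psgs": n_psg, "n_sites": n_sites,
                "n_psgs_with_fixed_site": n_fixed_psg,
                "n_fixed_sites": n_fixed_sites,
            })
        calls = pd.DataFrame(
            call_rows,
            columns=["gene_id", "branch", "aa_column", "fixed", "mode"])
        calls.to_csv(self._path("fixation.tsv"), sep="\t", index=False)
        pd.DataFrame(
            summary_rows,
            columns=["branch", "n_psgs", "n_sites",
                     "n_psgs_with_fixed_site", "n_fixed_sites"],
        ).to_csv(self._path("fixation_summary.tsv"), sep="\t", index=False)
        self._stage_results["fixation"] = calls
        return calls

    # -- stage 6: expression ----------------------------------------------
    def stage_expression(self, resume: bool = True) -> pd.DataFrame:
        if "expression" in self._stage_results:
            return self._stage_results["expression"]
        if resume and self._done("tau.tsv", "pair_comparison.tsv"):
            self._stage_results["expression"] = pd.read_csv(
                self._path("pair_comparison.tsv"), sep="\t")
            return self._stage_results["expression"]
        psg_table = self.stage_filter(resume)
        expr_raw = pd.read_csv(self.dataset / "expression.tsv", sep="\t",
                               index_col=0)
        matrix = log_transform(ExpressionMatrix(expr_raw))
        taus = tau_table(matrix)
        taus.to_csv(self._path("tau.tsv"), sep="\t", index=False,
                   float_format="%.12g")
        family_map = read_family_map(self.dataset / "family_map.tsv")
        proteins = {}
        for gene in expr_raw.index:
            fasta = self.dataset / "proteins" / f"{gene}.aln.fasta"
            if not fasta.exists():
                continue
            from Bio import SeqIO

            for rec in SeqIO.parse(str(fasta), "fasta"):
                if rec.id == "human":
                    proteins[gene] = str(rec.seq).replace("-", "")
        psgs = sorted(set(psg_table[psg_table.final_psg].gene_id))
        tau_by_gene = dict(zip(taus.gene_id, taus.tau))
        mean_by_gene = dict(zip(taus.gene_id, taus.mean_expression))
        pairs = build_pairs(psgs, family_map, proteins, tau_by_gene,
                            mean_by_gene)
        pair_frame, summary = compare_pairs(pairs)
        pair_frame.to_csv(self._path("pair_comparison.tsv"), sep="\t",
                          index=False,
                   float_format="%.12g")
        with open(self._path("expression_summary.yaml"), "w") as fh:
            yaml.safe_dump(summary, fh)
        self._stage_results["expression"] = pair_frame
        return pair_frame

    # -- stage 7: association ---------------------------------------------
    def stage_associate(self, resume: bool = True) -> pd.DataFrame:
        if "associate" in self._stage_results:
            return self._stage_results["associate"]
        if resume and self._done("multigene_association.tsv",
                                 "disease_association.tsv"):
            self._stage_results["associate"] = pd.read_csv(
                self._path("multigene_association.tsv"), sep="\t")
            return self._stage_results["associate"]
        psg_table = self.stage_filter(resume)
        universe = self.stage_qc(resume)["gene_id"].tolist()
        family_map = read_family_map(self.dataset / "family_map.tsv")
        sizes = family_map.groupby("family_id")["gene_id"].count()
        fam_of = dict(zip(family_map.gene_id, family_map.family_id))
        # each ortholog group contributes one member per species, so a
        # family is multigene iff it contains >= 2 ortholog groups
        family_class = {
            g: classify_family({
                taxon: tuple(
                    family_map[family_map.family_id == fam_of[g]].gene_id)
                for taxon in GREAT_APE_TAXA
            })
            for g in universe if g in fam_of
        }
        rows = []
        for branch in self.config.foreground_branches:
            psgs = set(psg_table[(psg_table.final_psg)
                                 & (psg_table.branch == branch)].gene_id)
            table, result, detail = multigene_association(
                psgs, family_class, universe, branch)
            rows.append({
                "branch": branch,
                "n_psg_multigene": table.a, "n_non_psg_multigene": table.b,
                "n_psg_single": table.c, "n_non_psg_single": table.d,
                "proportion_psg_multigene": detail["proportion_psg_multigene"],
                "proportion_psg_single": detail["proportion_psg_single"],
                "pvalue": result.pvalue, "pvalue_3dp": detail["pvalue_3dp"],
            })
        multi = pd.DataFrame(rows)
        multi.to_csv(self._path("multigene_association.tsv"), sep="\t",
                     index=False,
                   float_format="%.12g")

        disease = set(pd.read_csv(self.dataset / "disease_genes.tsv",
                                  sep="\t")["gene_id"])
        branch = self.config.disease_branch
        psgs = set(psg_table[(psg_table.final_psg)
                             & (psg_table.branch == branch)].gene_id)
        if psgs:
            table, result, detail = disease_association(psgs, disease,
                                                        universe)
            dis_row = {
                "branch": branch,
                "n_psg_disease": table.a, "n_psg_non_disease": table.b,
                "n_non_psg_disease": table.c, "n_non_psg_non_disease": table.d,
                "proportion_disease_psg": detail["proportion_disease_psg"],
                "proportion_disease_non_psg":
                    detail["proportion_disease_non_psg"],
                "pvalue": result.pvalue, "pvalue_3dp": detail["pvalue_3dp"],
            }
        else:
            dis_row = {"branch": branch, "n_psg_disease": 0,
                       "n_psg_non_disease": 0,
                       "n_non_psg_disease": len(disease & set(universe)),
                       "n_non_psg_non_disease":
                           len(universe) - len(disease & set(universe)),
                       "proportion_disease_psg": None,
                       "proportion_disease_non_psg": None,
                       "pvalue": 1.0, "pvalue_3dp": 1.0}
        pd.DataFrame([dis_row]).to_csv(self._path("disease_association.tsv"),
                                       sep="\t", index=False,
                   float_format="%.12g")
        self._stage_results["associate"] = multi
        return multi


def run_scan(config: PipelineConfig, stages: tuple[str, ...] = STAGES,
             resume: bool = True) -> dict[str, pd.DataFrame]:
    """Run the requested stages in canonical order; returns their tables."""
    run = ScanRun(config)
    results: dict[str, pd.DataFrame] = {}
    for stage in STAGES:
        if stage not in stages:
            continue
        method = getattr(run, f"stage_{stage}")
        try:
            results[stage] = method(resume=resume)
        except Exception as exc:  # pragma: no cover - error surface
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    config.to_yaml(run.out / "config.yaml")
    manifest = {
        "stages": list(stages),
        "outputs": sorted(p.name for p in run.out.iterdir() if p.is_file()),
    }
    with open(run.out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh)
    return results
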