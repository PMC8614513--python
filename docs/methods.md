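# Methods

`apescan` re-implements, as one tested pipeline, a genome-scale scan for
positively selected genes (PSGs) in great apes: branch-site codon-model
likelihood-ratio tests over one-to-one orthologs of six primates, a
four-stage false-positive filter cascade, population-fixation calls for
the selected sites, a tissue-specificity comparison of PSGs against
their closest paralogs, and exact Fisher association tests.  Because the
original inputs (genome assemblies, externally computed alignments and
population VCFs) are not redistributable at desk scale, the package
ships a first-class synthetic-data generator that emulates every input
with the statistical structure the analysis assumes, so the whole
pipeline runs and is validated end-to-end.

## Codon substitution model

The engine is a Goldman–Yang style Markov model on the 61 sense codons
of the universal code.  Off-diagonal rates for single-nucleotide changes
are `q_ij = π_j · κ^[transition] · ω^[nonsynonymous]`; multi-nucleotide
changes have rate 0.  κ is the transition/transversion ratio, ω = dN/dS,
and π the stationary codon frequencies, estimated from the alignment
under F3x4 by default (F1x4 and F61 selectable).  F3x4 and F61 use a 0.5
pseudo-count per cell so sparse alignments never produce zero
frequencies.

**Scaling.**  In mixture models every class matrix is divided by the
stationary rate of the *neutral* (ω = 1) matrix at the same κ and π.
One unit of branch length is therefore one expected substitution for a
neutral site, and a class with ω = 8 genuinely evolves ≈ 6–7× faster —
the rate excess on the foreground branch that the branch-site test
detects.  (Normalising each class matrix to unit rate individually would
leave only a compositional signal and destroys essentially all power;
this was measured, not assumed.)  The simulator uses the identical
convention, so simulated branch lengths and fitted ones are directly
comparable.  The standalone `build_rate_matrix` defaults to the
conventional per-matrix unit scaling.

Transition probabilities come from the spectral decomposition of the
symmetrised generator (the model is reversible), so P(t) for all
branches of a tree costs one eigendecomposition per (κ, ω).

## Likelihood

Felsenstein pruning over site patterns (identical columns collapsed,
counted by weights).  Gap codons (`---`) and N-containing codons are
treated as missing data for that sequence only — the tip partial is a
vector of ones — never by deleting the column.  An all-gap column
contributes log 1 = 0 and is flagged.  Per-class conditional site
likelihoods are cached by (κ, ω_bg, ω_fg, branch lengths, foreground
set); mixture weights only re-weight cached vectors, which makes
finite-difference optimisation cheap in the weight directions.

## Fits and tests

* **M0 (one-ratio)** — κ, a single ω, and all 9 branch lengths of the
  unrooted six-taxon tree are maximised jointly (L-BFGS-B in log space,
  two deterministic starts).  The fitted tree seeds all later fits.
* **Branch-site test** — model A: four site classes (0, 1, 2a, 2b) with
  proportions `(p0, p1, p2a, p2b)` constrained by
  `p2a = (1−p0−p1)·p0/(p0+p1)` (and symmetrically for `p2b`), ω1 = 1
  fixed, ω0 ∈ (0,1) shared, and ω2 ∈ [1, 999] applying on the designated
  foreground branch in classes 2a/2b.  The null fixes ω2 = 1; the LRT
  uses χ²₁ by default (conservative; the 50:50 mixture reference is a
  flag).  Optimisation is joint over transformed
  (log κ, logit ω0, log(ω2−1), log t_fg, logit q, logit s) where
  (q, s) = (p0/(p0+p1), p0+p1); each fit runs three deterministic starts
  (two fixed points plus the nested fit's solution) and the null is
  re-polished from the alternative's solution whenever the test is
  anywhere near the rejection region, so neither hypothesis is
  under-optimised relative to the other.
* **Foreground branch length.**  Background branch lengths are fixed at
  the M0 estimates, but the foreground branch length is re-estimated
  inside both the null and alternative fits (one extra shared
  parameter; the LRT df is unchanged).  This deviates from fixing *all*
  lengths at M0: under strong foreground selection the single-ω M0
  inflates precisely the foreground edge, absorbing the rate excess the
  test needs — with fully fixed lengths, measured power at ω2 = 8
  dropped from ≈ 0.9 to ≈ 0.3 and site identification to zero.
* **BEB site posteriors** — empirical-Bayes posterior that a column
  belongs to class 2a∪2b, integrating over a fixed grid prior:
  45 triangular points `((i+0.5)/10, (j+0.5)/10)` on the (p0, p1)
  simplex, 10 midpoints of (0,1) for ω0 and 10 midpoints of (1,11) for
  ω2, all equally weighted, with κ and branch lengths at the
  alternative-fit MLEs.  Grid points are weighted by the likelihood of
  the whole alignment; sites with posterior strictly above 0.95 form the
  selected-site list.
* **Relaxation (K) test** — labelled `relax_style` in every output: a
  deliberate simplification of the published RELAX framework, with three
  shared site classes (ω0 < 1, 1, ω2 ≥ 1) on reference branches and
  every class ω raised to a single power K on the test branches
  (capped at 999 after exponentiation).  K = 1 is the null (df = 1);
  K < 1 indicates relaxed selection.  The test-branch length is
  re-estimated in both fits, as above.  No bit-compatibility with the
  external RELAX implementation is claimed.

On branch-site data simulated with strong positive selection, the
K test is bimodal: most replicates land in an "intensification" mode
(K̂ at the upper bound with ω2 ≈ 1), a minority in a "relaxation" mode
(K̂ near the lower bound) that the drift filter then removes.  This is
an intrinsic property of summarising a branch-site generative process
with a single selection-intensity exponent, and it is why a small
fraction of genuinely selected synthetic genes is lost at the
relaxation stage.

## Filter cascade

A gene × branch test is a **candidate** iff the LRT p < 0.05 (strict)
and at least one site has BEB posterior > 0.95 (strict).  Candidates
then pass, in order: (1) the gap-proximity filter — a selected site
fails if *any* taxon has an alignment gap within 5 amino-acid columns
(inclusive; the site's own column counts), and one failing site removes
the gene (mode `any`; mode `all`, which keeps a gene with at least one
clean site, is available); (2) the column-score filter — every selected
site's alignment-confidence column score must be ≥ 1.0, i.e. maximal;
(3) the relaxation filter — the gene is removed iff K < 1 *and* the K
test's p < 0.05.  An unavailable or unconverged relaxation fit passes
with a warning rather than silently dropping the gene.  Gaps are counted
in any taxon's row (alignment error at a column affects all rows); both
that choice and site- vs gene-level removal are configuration switches.
No multiple-testing correction is applied across the seven
branch-labelings per gene, matching the original procedure.

## Fixation calls

Selected sites are mapped per species from alignment columns to
ungapped protein positions and then, through the species' CDS gene
model (1-based GFF3 coordinates, strand- and intron-aware), to the
three genomic positions of the codon.  With per-allele frequencies, a
site is fixed iff the analysis-assembly allele (the VCF reference
allele — the only allele identifiable without phasing) has frequency
> 0.95 at every variant overlapping the codon; without frequencies, iff
no overlapping variant carries an alternative allele; a codon with no
overlapping variants is fixed.  Indels and multi-nucleotide variants
count as alternative alleles (conservative).  A PSG is fixed if at
least one of its selected sites is fixed.  For stem-branch PSGs the
pipeline requires the site to be fixed in every descendant great-ape
population; terminal branches use their own species' population.
Variants must already be on the analysis assembly — cross-assembly
liftover is out of scope.

## Expression and association

Expression is log2(TPM+1), applied exactly once (the matrix carries a
transform flag).  Tissue specificity is τ = Σᵢ(1 − xᵢ/max x)/(n−1) on
the transformed profile (0 = uniform, 1 = single-tissue; undefined for
all-zero profiles).  Each PSG in a multigene family is paired with the
non-PSG family member of highest global protein identity
(matches / alignment length under BLOSUM62, gap open −10 / extend −0.5;
ties break toward longer alignments, then the smaller gene id), and
pairs are compared by strict inequality on τ and on mean expression.

Association tests are exact one-sided hypergeometric upper tails
(over-representation of the a-cell) on 2×2 tables over the retained
ortholog universe: PSG × multigene-family membership per branch, and
PSG × disease-gene status.  A family is multigene iff any species
contributes ≥ 2 members.  Reported p-values and proportions are rounded
half-up to 3 decimals; raw values are retained.

## Synthetic data generator

The generator is the package's study stand-in, not a fixture: codon
alignments evolve by drawing a class per site and simulating the
class- and branch-appropriate substitution process down the fixed
six-primate topology `(((((human, chimpanzee), gorilla), orangutan),
gibbon), rhesus)`.  Defaults: 300 codons; κ = 2; uniform codon
frequencies; class proportions p0 = p1 = 0.35 (30% of sites in the
selected classes); ω0 = 0.2; ω2 = 8 for PSG genes and 1 for the rest;
branch lengths (neutral substitutions/codon) human and chimpanzee 0.25,
gorilla 0.30, orangutan 0.35, gibbon 0.45, rhesus 0.50, and 0.10, 0.10,
0.15 for the Hominini, Homininae and Hominidae stems.  These are
deliberately deeper than real great-ape divergence and carry a larger
selected-site fraction than a typical gene: the defaults are chosen for
*testability* — enough signal that power, calibration and site
identification are measurable with hundreds of replicates on one CPU —
not as a demographic portrait of the clade.  Consequently, passing
tests demonstrate correctness and calibration of the machinery, not the
expected yield of a real scan, where effect sizes are smaller, most
genes are null, and alignment error is structured rather than random.

Other components: gap runs are injected per-taxon at amino-acid
granularity (`---` codons, masked as missing, never deleted);
alignment-confidence column scores are sampled (a fraction of columns
score < 1.0, uniformly in [0.50, 0.99], the rest exactly 1.0) rather
than recomputed from alignment replicates; family sizes follow a
truncated geometric distribution (p = 0.45, max 6 ortholog groups per
family); expression profiles are single-tissue dominant (200–1000 TPM
in one tissue, < 0.5 elsewhere) or near-uniform (lognormal jitter
around 20–200 TPM); population variants are placed inside selected
codons so that per-site fixation flags round-trip exactly through the
caller, with alternative-allele frequencies ≤ 0.04 at fixed sites and
0.10–0.60 at non-fixed ones; gene models are laid along a synthetic
chromosome, every third gene with a codon-splitting intron.  The number
of PSGs is `round(psg_fraction × n_genes)` with ties up.  All
randomness descends from one integer seed through named substreams, so
every stage is independently reproducible.

## Numerical choices and degenerate inputs

Convergence: relative log-likelihood change below 1e-8 (L-BFGS-B
`ftol`), at most 400 iterations, bounds κ ∈ [0.05, 50],
ω2 − 1 ∈ [1e-8, 998], branch lengths ∈ [1e-7, 25].  Non-convergent fits
are flagged and treated as non-candidates (logged, never silently
dropped).  Likelihoods are floored at 1e-300 before logs.  Nested fits
whose optimised alternative falls below the null by optimiser tolerance
are clamped (statistic 0, p = 1).  Identical sequences yield ≈ 0 branch
lengths; an LRT statistic of exactly 3.841 yields p ≈ 0.050; a 2×2
table with an empty margin yields p = 1 with a warning.

## Problem sizes used in validation

The test suite validates the engine against exhaustive enumeration on
3-taxon/3-codon instances (tolerance 1e-8); LRT calibration on 200 null
and 50 selection replicates of 300-codon genes; K-test calibration on
100 null replicates of 400-codon genes (the test approaches its nominal
level from above as alignments grow; at 150–200 codons it is measurably
anticonservative, so calibration is assessed at a realistic CDS length
— the median human CDS is ≈ 500 codons); BEB ranking on 20 replicates;
and an end-to-end 20-gene, 300-codon study checked for completion,
byte-level determinism and planted-gene recovery.  These sizes are the
package's validation design; the generator and pipeline accept
arbitrary sizes.

## Known limitations

* The relax-style test is a single-K simplification; its K estimates on
  branch-site-type data are bimodal (see above), and it is mildly
  anticonservative on short (< 200 codon) alignments.
* The branch-site LRT with the χ²₁ reference is near-nominal rather
  than conservative under these generator settings (deep tree, large
  selected-site fraction); the 50:50 mixture reference would be
  anticonservative here and is off by default.
* GUIDANCE-style column scores are sampled, not recomputed from
  alignment replicates; gap patterns are random, not phylogenetically
  structured.
* Ortholog inference, protein alignment, gene-family clustering and
  cross-assembly liftover are consumed as inputs, never recomputed.
* The fixation caller equates "the selected allele" with the analysis
  assembly's reference allele; without phasing or ancestral
  polarisation this is the only identifiable choice.
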