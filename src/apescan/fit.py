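"""Maximum-likelihood fits: M0, branch-site test, and relaxation test.

Fitting strategy
----------------
All fits maximise the pruning likelihood of :class:`~apescan.likelihood.
TreeLikelihood` with a quasi-Newton optimiser in transformed coordinates
(log for κ, ω and branch lengths; logit for ω0; log(ω2−1) for the
selection class).  Because per-class site likelihoods do not depend on
the mixture weights, the class proportions are profiled out: for every
trial of the outer parameters the weights are driven to their conditional
optimum by a closed-form EM inner loop.  The branch-site weight
constraint (p0, p1, p2a, p2b) = (qs, (1−q)s, q(1−s), (1−q)(1−s)) with
s = p0+p1 and q = p0/(p0+p1) makes that inner problem a 2-D factorised
mixture with closed-form EM updates.

Branch lengths are estimated once under M0 (single ω shared by all sites
and branches) and held fixed for the branch-site and relaxation fits.
Each fit starts from a fixed set of deterministic initial points; the
best final likelihood wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit
from scipy.stats import chi2

from .alignment import CodonAlignment
from .codonmodel import (
    N_CODONS,
    SENSE_CODONS,
    f1x4_frequencies,
    f3x4_frequencies,
    f61_frequencies,
)
from .likelihood import SiteClass, TreeLikelihood
from .trees import LabeledTree

OMEGA2_MAX = 999.0
_REL_TOL = 1e-8


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BranchSiteParameters:
    """Branch-site model A parameters with the derived class proportions."""

    p0: float
    p1: float
    omega0: float
    omega2: float

    def __post_init__(self):
        if not (0 <= self.p0 and 0 <= self.p1 and self.p0 + self.p1 <= 1 + 1e-12):
            raise ValueError("proportions must satisfy p0,p1>=0, p0+p1<=1")
        if not (0 < self.omega0 < 1):
            raise ValueError("omega0 must lie in (0,1)")
        if self.omega2 < 1:
            raise ValueError("omega2 must be >= 1")

    @property
    def p2a(self) -> float:
        s = self.p0 + self.p1
        return (1 - s) * self.p0 / s if s > 0 else 0.0

    @property
    def p2b(self) -> float:
        s = self.p0 + self.p1
        return (1 - s) * self.p1 / s if s > 0 else 0.0

    def weights(self) -> np.ndarray:
        return np.array([self.p0, self.p1, self.p2a, self.p2b])

    def site_classes(self) -> list[SiteClass]:
        """Class-to-ω map: 0→(ω0,ω0), 1→(1,1), 2a→(ω0,ω2), 2b→(1,ω2)."""
        return [
            SiteClass(self.p0, self.omega0, self.omega0),
            SiteClass(self.p1, 1.0, 1.0),
            SiteClass(self.p2a, self.omega0, self.omega2),
            SiteClass(self.p2b, 1.0, self.omega2),
        ]


@dataclass
class FitResult:
    model: str
    loglik: float
    kappa: float
    converged: bool
    n_starts: int
    tree: LabeledTree | None = None
    omega: float | None = None                      # M0
    params: BranchSiteParameters | None = None      # branch-site
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not np.isfinite(self.loglik):
            self.converged = False


@dataclass(frozen=True)
class FitComparison:
    """Likelihood-ratio test of nested fits."""

    loglik_alt: float
    loglik_null: float
    statistic: float
    df: int
    pvalue: float


@dataclass
class RelaxFit:
    """Selection-intensity (K) test: foreground ω's raised to the power K."""

    k: float
    loglik_alt: float
    loglik_null: float
    pvalue: float
    converged: bool
    model: str = "relax_style"
    params_alt: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Codon frequency estimation
# ---------------------------------------------------------------------------

def estimate_pi(alignment: CodonAlignment, model: str = "F3x4") -> np.ndarray:
    """Equilibrium codon frequencies from the alignment (F3x4 default)."""
    observed = alignment.codes[alignment.codes >= 0]
    if model == "F61":
        counts = np.bincount(observed, minlength=N_CODONS)
        return f61_frequencies(counts)
    nuc_idx = {"T": 0, "C": 1, "A": 2, "G": 3}
    pos_counts = np.zeros((3, 4))
    for code in observed:
        codon = SENSE_CODONS[code]
        for pos, nuc in enumerate(codon):
            pos_counts[pos, nuc_idx[nuc]] += 1
    if model == "F3x4":
        return f3x4_frequencies(pos_counts)
    if model == "F1x4":
        return f1x4_frequencies(pos_counts.sum(axis=0))
    raise ValueError(f"unknown frequency model {model!r}")


# ---------------------------------------------------------------------------
# Inner weight optimisation (EM, closed-form updates)
# ---------------------------------------------------------------------------

def _em_qs(F: np.ndarray, counts: np.ndarray, q0=0.7, s0=0.8,
           max_iter=500, tol=1e-10) -> tuple[float, float, float]:
    """Maximise Σ counts·log(w(q,s)·F) over (q,s) ∈ (0,1)²."""
    q, s = q0, s0
    last = -np.inf
    n_total = counts.sum()
    for _ in range(max_iter):
        w = np.array([q * s, (1 - q) * s, q * (1 - s), (1 - q) * (1 - s)])
        mix = w @ F
        mix = np.maximum(mix, 1e-300)
        ll = float(counts @ np.log(mix))
        resp = (w[:, None] * F) / mix[None, :]
        n_c = resp @ counts
        q = float(np.clip((n_c[0] + n_c[2]) / n_total, 1e-9, 1 - 1e-9))
        s = float(np.clip((n_c[0] + n_c[1]) / n_total, 1e-9, 1 - 1e-9))
        if ll - last < tol * max(1.0, abs(ll)):
            last = ll
            break
        last = ll
    return q, s, last


def _em_simplex(F: np.ndarray, counts: np.ndarray, w0=None,
                max_iter=500, tol=1e-10) -> tuple[np.ndarray, float]:
    """Maximise Σ counts·log(w·F) over the simplex (plain mixture EM)."""
    k = F.shape[0]
    w = np.full(k, 1.0 / k) if w0 is None else np.asarray(w0, dtype=float)
    last = -np.inf
    n_total = counts.sum()
    for _ in range(max_iter):
        mix = np.maximum(w @ F, 1e-300)
        ll = float(counts @ np.log(mix))
        resp = (w[:, None] * F) / mix[None, :]
        w = np.clip((resp @ counts) / n_total, 1e-12, None)
        w /= w.sum()
        if ll - last < tol * max(1.0, abs(ll)):
            last = ll
            break
        last = ll
    return w, last


# ---------------------------------------------------------------------------
# M0 fit (κ, ω, branch lengths)
# ---------------------------------------------------------------------------

_M0_STARTS = ((2.0, 0.2), (2.0, 1.0))


def fit_M0(
    alignment: CodonAlignment,
    tree: LabeledTree,
    pi: np.ndarray | None = None,
    engine: TreeLikelihood | None = None,
) -> FitResult:
    """One-ratio fit: shared ω, κ, and all branch lengths free."""
    if pi is None:
        pi = estimate_pi(alignment)
    if engine is None:
        engine = TreeLikelihood(alignment, tree, pi)
    init_lengths = np.maximum(tree.length_vector(), 1e-4)

    def objective(x: np.ndarray) -> float:
        kappa = np.exp(x[0])
        omega = np.exp(x[1])
        lengths = np.exp(x[2:])
        f = engine.class_site_likelihoods(kappa, omega, omega, lengths,
                                          frozenset())
        ll = float(engine.pattern_weights @ np.log(np.maximum(f, 1e-300)))
        return -ll

    bounds = ([(np.log(0.05), np.log(50.0)), (np.log(1e-4), np.log(40.0))]
              + [(np.log(1e-7), np.log(25.0))] * len(init_lengths))
    best = None
    for kappa0, omega0 in _M0_STARTS:
        x0 = np.concatenate([[np.log(kappa0), np.log(omega0)],
                             np.log(init_lengths)])
        res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                       options={"ftol": _REL_TOL, "maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
    kappa = float(np.exp(best.x[0]))
    omega = float(np.exp(best.x[1]))
    lengths = np.exp(best.x[2:])
    fitted_tree = tree.with_length_vector(lengths)
    return FitResult(
        model="M0",
        loglik=-float(best.fun),
        kappa=kappa,
        omega=omega,
        tree=fitted_tree,
        converged=bool(np.isfinite(best.fun)),
        n_starts=len(_M0_STARTS),
    )


# ---------------------------------------------------------------------------
# Branch-site fits
# ---------------------------------------------------------------------------

_BS_STARTS_ALT = ((2.0, 0.5, 8.0), (4.0, 0.05, 1.2))
_BS_STARTS_NULL = ((2.0, 0.2), (4.0, 0.05))


def _branch_site_class_matrix(engine, kappa, omega0, omega2, lengths, fg):
    """Per-class site likelihoods, rows = classes (0, 1, 2a, 2b)."""
    return np.stack([
        engine.class_site_likelihoods(kappa, omega0, omega0, lengths, fg),
        engine.class_site_likelihoods(kappa, 1.0, 1.0, lengths, fg),
        engine.class_site_likelihoods(kappa, omega0, omega2, lengths, fg),
        engine.class_site_likelihoods(kappa, 1.0, omega2, lengths, fg),
    ])


def fit_branch_site(
    alignment: CodonAlignment,
    tree: LabeledTree,
    null: bool = False,
    pi: np.ndarray | None = None,
    engine: TreeLikelihood | None = None,
    extra_starts: tuple = (),
    free_foreground_length: bool = True,
    only_extra_starts: bool = False,
) -> FitResult:
    """Branch-site model A fit.

    Alternative: ω2 free in [1, 999]; null: ω2 fixed at 1.  Background
    branch lengths stay at the values of the supplied tree (the M0
    estimates); the foreground branch length is re-estimated inside both
    fits by default — a single-ω M0 estimate of that edge soaks up the
    very rate excess the test looks for, so holding it fixed destroys
    power against strong selection.  ``free_foreground_length=False``
    restores the fully fixed-lengths variant.
    """
    if not tree.foreground:
        raise ValueError("tree must designate a foreground branch")
    if pi is None:
        pi = estimate_pi(alignment)
    if engine is None:
        engine = TreeLikelihood(alignment, tree, pi)
    base_lengths = tree.length_vector()
    fg = tree.foreground_nodes()
    fg_edges = sorted(fg)
    counts = engine.pattern_weights
    t_fg0 = max(float(np.mean([base_lengths[e] for e in fg_edges])), 1e-4)

    # x = (log κ, logit ω0, [log(ω2−1)], [log t_fg], logit q, logit s);
    # class proportions are (qs, (1−q)s, q(1−s), (1−q)(1−s)).
    def unpack(x):
        kappa = np.exp(x[0])
        omega0 = expit(x[1])
        omega2 = 1.0 if null else 1.0 + np.exp(x[2])
        if free_foreground_length:
            lengths = base_lengths.copy()
            for e in fg_edges:
                lengths[e] = np.exp(x[-3])
        else:
            lengths = base_lengths
        q = expit(x[-2])
        s = expit(x[-1])
        return kappa, omega0, omega2, lengths, q, s

    def negloglik(x: np.ndarray) -> float:
        kappa, omega0, omega2, lengths, q, s = unpack(x)
        F = _branch_site_class_matrix(engine, kappa, omega0, omega2,
                                      lengths, fg)
        w = np.array([q * s, (1 - q) * s, q * (1 - s), (1 - q) * (1 - s)])
        mix = np.maximum(w @ F, 1e-300)
        return -float(counts @ np.log(mix))

    weight_starts = (0.7, 0.85)
    t_block = [np.log(t_fg0)] if free_foreground_length else []
    t_bounds = ([(np.log(1e-7), np.log(25.0))]
                if free_foreground_length else [])
    if null:
        starts = [] if only_extra_starts else [
            np.array([np.log(k), logit(w0)] + t_block
                     + [logit(weight_starts[0]), logit(weight_starts[1])])
            for k, w0 in _BS_STARTS_NULL
        ]
        for k, w0, t, q0, s0 in extra_starts:
            starts.append(np.array(
                [np.log(k), logit(w0)]
                + ([np.log(max(t, 1e-7))] if free_foreground_length else [])
                + [logit(np.clip(q0, 1e-6, 1 - 1e-6)),
                   logit(np.clip(s0, 1e-6, 1 - 1e-6))]))
        bounds = ([(np.log(0.05), np.log(50.0)), (logit(1e-5), logit(0.999))]
                  + t_bounds + [(-13.0, 13.0), (-13.0, 13.0)])
    else:
        starts = [] if only_extra_starts else [
            np.array([np.log(k), logit(w0), np.log(max(w2 - 1.0, 1e-6))]
                     + t_block
                     + [logit(weight_starts[0]), logit(weight_starts[1])])
            for k, w0, w2 in _BS_STARTS_ALT
        ]
        for k, w0, w2, t, q0, s0 in extra_starts:
            starts.append(np.array(
                [np.log(k), logit(w0), np.log(max(w2 - 1.0, 1e-6))]
                + ([np.log(max(t, 1e-7))] if free_foreground_length else [])
                + [logit(np.clip(q0, 1e-6, 1 - 1e-6)),
                   logit(np.clip(s0, 1e-6, 1 - 1e-6))]))
        bounds = ([(np.log(0.05), np.log(50.0)), (logit(1e-5), logit(0.999)),
                   (np.log(1e-8), np.log(OMEGA2_MAX - 1.0))]
                  + t_bounds + [(-13.0, 13.0), (-13.0, 13.0)])

    best = None
    for x0 in starts:
        res = minimize(negloglik, x0, method="L-BFGS-B",
                       bounds=bounds, options={"ftol": _REL_TOL, "maxiter": 400})
        if best is None or res.fun < best.fun:
            best = res

    kappa, omega0, omega2, lengths, q, s = unpack(best.x)
    params = BranchSiteParameters(p0=q * s, p1=(1 - q) * s,
                                  omega0=float(omega0), omega2=float(omega2))
    fitted_tree = tree.with_length_vector(lengths)
    return FitResult(
        model="branch_site_null" if null else "branch_site_alt",
        loglik=-float(best.fun),
        kappa=float(kappa),
        params=params,
        tree=fitted_tree,
        converged=bool(np.isfinite(best.fun) and best.status != 2),
        n_starts=len(starts),
        extra={"foreground_length": float(lengths[fg_edges[0]])},
    )


def lrt(loglik_alt: float, loglik_null: float, df: int = 1,
        null_distribution: str = "chi2") -> FitComparison:
    """Likelihood-ratio test: 2Δℓ (clamped at 0) against χ²_df.

    ``null_distribution='mixture'`` uses the 50:50 mix of χ²₀ and χ²₁
    (halves the tail p); the default χ²₁ reference is conservative.
    """
    if not (np.isfinite(loglik_alt) and np.isfinite(loglik_null)):
        raise ValueError("log-likelihoods must be finite")
    stat = max(0.0, 2.0 * (loglik_alt - loglik_null))
    p = float(chi2.sf(stat, df))
    if null_distribution == "mixture":
        p = 1.0 if stat == 0.0 else 0.5 * p
    elif null_distribution != "chi2":
        raise ValueError(f"unknown null distribution {null_distribution!r}")
    return FitComparison(loglik_alt=loglik_alt, loglik_null=loglik_null,
                         statistic=stat, df=df, pvalue=min(max(p, 5e-324), 1.0))


def branch_site_test(
    alignment: CodonAlignment,
    tree: LabeledTree,
    pi: np.ndarray | None = None,
    engine: TreeLikelihood | None = None,
    null_distribution: str = "chi2",
) -> tuple[FitResult, FitResult, FitComparison]:
    """Fit alternative and null branch-site models and run the LRT.

    The null solution is recycled as an extra starting point of the
    alternative fit, which guarantees ℓ_alt ≥ ℓ_null up to optimiser
    tolerance.
    """
    if pi is None:
        pi = estimate_pi(alignment)
    if engine is None:
        engine = TreeLikelihood(alignment, tree, pi)
    null_fit = fit_branch_site(alignment, tree, null=True, pi=pi, engine=engine)
    p = null_fit.params
    s0 = p.p0 + p.p1
    q0 = p.p0 / s0 if s0 > 0 else 0.5
    seed = (null_fit.kappa, p.omega0, 1.0 + 1e-6,
            null_fit.extra.get("foreground_length", 0.1), q0, s0)
    alt_fit = fit_branch_site(alignment, tree, null=False, pi=pi,
                              engine=engine, extra_starts=(seed,))
    # polish the null from the alternative's solution (ω2 dropped): an
    # under-optimised null inflates the LRT statistic.  The polish can
    # only shrink the statistic, so it is run only when the unpolished
    # test is anywhere near the rejection region.
    if lrt(alt_fit.loglik, null_fit.loglik).pvalue < 0.25:
        ap = alt_fit.params
        alt_s = ap.p0 + ap.p1
        alt_q = ap.p0 / alt_s if alt_s > 0 else 0.5
        null_seed = (alt_fit.kappa, ap.omega0,
                     alt_fit.extra.get("foreground_length", 0.1),
                     alt_q, alt_s)
        null_polish = fit_branch_site(alignment, tree, null=True, pi=pi,
                                      engine=engine,
                                      extra_starts=(null_seed,),
                                      only_extra_starts=True)
        if null_polish.loglik > null_fit.loglik:
            null_fit = null_polish
    if alt_fit.loglik < null_fit.loglik:
        # optimiser tolerance only: the models are nested
        alt_fit.loglik = null_fit.loglik
    comparison = lrt(alt_fit.loglik, null_fit.loglik, df=1,
                     null_distribution=null_distribution)
    return alt_fit, null_fit, comparison


# ---------------------------------------------------------------------------
# Relaxation (K) test
# ---------------------------------------------------------------------------

_RELAX_STARTS = ((2.0, 0.2, 2.5, 0.3), (2.0, 0.5, 8.0, 3.0))


def _relax_class_matrix(engine, kappa, omega0, omega2, k, lengths, fg):
    """Three shared classes; test-branch ω's raised to the power K."""
    omegas = (omega0, 1.0, omega2)
    return np.stack([
        engine.class_site_likelihoods(kappa, w, min(w ** k, OMEGA2_MAX),
                                      lengths, fg)
        for w in omegas
    ])


def fit_relax_style(
    alignment: CodonAlignment,
    tree: LabeledTree,
    pi: np.ndarray | None = None,
    engine: TreeLikelihood | None = None,
) -> RelaxFit:
    """Selection-intensity test in the spirit of RELAX.

    Three site classes with ω0 < 1, ω1 = 1, ω2 ≥ 1 are shared by all
    branches; on the test (foreground) branches every class ω is raised
    to the power K.  K is free in the alternative and fixed at 1 in the
    null; the LRT has one degree of freedom.  K < 1 indicates relaxed
    selection.  This is a simplified re-implementation (single K, three
    classes) and is labeled ``relax_style`` in all outputs; it does not
    claim bit-compatibility with the published RELAX.
    """
    if not tree.foreground:
        raise ValueError("tree must designate a test (foreground) branch")
    if pi is None:
        pi = estimate_pi(alignment)
    if engine is None:
        engine = TreeLikelihood(alignment, tree, pi)
    base_lengths = tree.length_vector()
    fg = tree.foreground_nodes()
    fg_edges = sorted(fg)
    counts = engine.pattern_weights
    t_fg0 = max(float(np.mean([base_lengths[e] for e in fg_edges])), 1e-4)

    # x = (log κ, logit ω0, log(ω2−1), [log K], log t_fg, a1, a2);
    # weights = softmax(0, a1, a2); the test-branch length is
    # re-estimated for the same reason as in the branch-site fits.
    def negloglik(x: np.ndarray, fixed_k: float | None) -> float:
        kappa = np.exp(x[0])
        omega0 = expit(x[1])
        omega2 = 1.0 + np.exp(x[2])
        k = fixed_k if fixed_k is not None else np.exp(x[3])
        lengths = base_lengths.copy()
        for e in fg_edges:
            lengths[e] = np.exp(x[-3])
        logits = np.array([0.0, x[-2], x[-1]])
        w = np.exp(logits - logits.max())
        w /= w.sum()
        F = _relax_class_matrix(engine, kappa, omega0, omega2, k, lengths, fg)
        mix = np.maximum(w @ F, 1e-300)
        return -float(counts @ np.log(mix))

    def run(fixed_k: float | None, extra_start=None, only_extra=False):
        bounds = [(np.log(0.05), np.log(50.0)), (logit(1e-5), logit(0.999)),
                  (np.log(1e-8), np.log(OMEGA2_MAX - 1.0))]
        starts = []
        if not only_extra:
            for kap, w0, w2, k in _RELAX_STARTS:
                x0 = [np.log(kap), logit(w0), np.log(max(w2 - 1.0, 1e-6))]
                if fixed_k is None:
                    x0.append(np.log(k))
                x0.extend([np.log(t_fg0), 0.0, -0.7])  # w ≈ (.42,.42,.21)
                starts.append(np.array(x0))
        if extra_start is not None:
            starts.append(np.asarray(extra_start))
        if fixed_k is None:
            bounds.append((np.log(0.02), np.log(50.0)))
        bounds.extend([(np.log(1e-7), np.log(25.0)),
                       (-13.0, 13.0), (-13.0, 13.0)])
        best = None
        for x0 in starts:
            res = minimize(negloglik, x0, args=(fixed_k,), method="L-BFGS-B",
                           bounds=bounds,
                           options={"ftol": _REL_TOL, "maxiter": 400})
            if best is None or res.fun < best.fun:
                best = res
        return best

    null_best = run(fixed_k=1.0)
    alt_seed = np.concatenate([null_best.x[:3], [0.0], null_best.x[3:]])
    alt_best = run(fixed_k=None, extra_start=alt_seed)
    # polish the null from the alternative's solution (K dropped) so the
    # two optimisations are equally thorough; an under-optimised null
    # inflates the statistic
    if lrt(max(-alt_best.fun, -null_best.fun), -null_best.fun).pvalue < 0.25:
        null_seed = np.concatenate([alt_best.x[:3], alt_best.x[4:]])
        null_polish = run(fixed_k=1.0, extra_start=null_seed,
                          only_extra=True)
        if null_polish.fun < null_best.fun:
            null_best = null_polish
    ll_alt, ll_null = -float(alt_best.fun), -float(null_best.fun)
    if ll_alt < ll_null:
        ll_alt = ll_null
    comparison = lrt(ll_alt, ll_null, df=1)
    k_hat = float(np.exp(alt_best.x[3]))
    return RelaxFit(
        k=k_hat,
        loglik_alt=ll_alt,
        loglik_null=ll_null,
        pvalue=comparison.pvalue,
        converged=bool(np.isfinite(ll_alt) and np.isfinite(ll_null)),
        params_alt={
            "kappa": float(np.exp(alt_best.x[0])),
            "omega0": float(expit(alt_best.x[1])),
            "omega2": float(1.0 + np.exp(alt_best.x[2])),
        },
    )
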