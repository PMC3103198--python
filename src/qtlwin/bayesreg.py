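"""Single-site Gibbs samplers for Bayesian whole-genome regression.

Implements the mixture model

    y = mu 1 + W s + u + sum_j X_j alpha_j delta_j + e

with variants differing in the prior on SNP effects:

* ``bayesCpi`` — common effect variance, pi (the probability a SNP has zero
  effect) estimated with a uniform prior;
* ``bayesC``   — common effect variance, pi fixed;
* ``bayesB``   — locus-specific effect variances, pi fixed;
* ``snp_blup`` — every SNP in the model with a common variance (equivalent to
  G-BLUP);
* ``pedigree_blup`` / animal models — no marker term, a correlated random
  effect with covariance sigma2_g * K for K = A or G.

delta_j and alpha_j are updated jointly (delta drawn with alpha integrated
out), which avoids the poor mixing of samplers that condition on alpha.
Fixed effects are parameterised identifiably as an intercept plus a female
contrast and given flat priors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import (sweep_loci, sweep_random_effect, quad_form,
                       sweep_random_effect_sparse, quad_form_sparse)

METHODS = ("bayesB", "bayesC", "bayesCpi", "snp_blup", "pedigree_blup")


@dataclass
class ModelSpec:
    method: str = "bayesCpi"
    pi: float | str = "estimated"       # fixed value, or "estimated" (BayesCpi)
    include_polygenic: bool = False
    prior_genetic_variance: float | None = None  # default: half the phenotypic variance
    nu_alpha: float = 4.2
    nu_e: float = 4.0
    nu_u: float = 4.0
    chain_length: int = 50_000
    burn_in: int = 20_000
    thin: int = 10
    seed: int = 0
    store_chain: bool = False
    check_every: int = 1000             # residual-identity refresh interval
    # hold a variance component fixed instead of sampling it (oracle checks,
    # model-equivalence runs at matched variances)
    sigma2_alpha_fixed: float | None = None
    sigma2_u_fixed: float | None = None
    sigma2_e_fixed: float | None = None
    # explicit prior scale overrides (otherwise derived from the data and
    # the prior genetic variance)
    prior_alpha_scale: float | None = None
    prior_residual_scale: float | None = None
    prior_u_scale: float | None = None

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.burn_in >= self.chain_length:
            raise ValueError("burn_in must be smaller than chain_length")
        if self.nu_alpha <= 0 or self.nu_e <= 0 or self.nu_u <= 0:
            raise ValueError("prior degrees of freedom must be positive")
        if isinstance(self.pi, str):
            if self.pi != "estimated":
                raise ValueError("pi must be a float or 'estimated'")
            if self.method in ("bayesB", "bayesC"):
                raise ValueError(f"{self.method} requires a fixed pi")
        else:
            if not 0.0 <= self.pi <= 1.0:
                raise ValueError("pi must lie in [0, 1]")

    def initial_pi(self) -> float:
        if self.method == "snp_blup":
            return 0.0
        if self.pi == "estimated":
            return 0.5
        return float(self.pi)


@dataclass
class PosteriorSummary:
    """Posterior means (and sds) over post-burn-in samples."""

    alpha_mean: np.ndarray
    alpha_sd: np.ndarray
    model_freq: np.ndarray            # posterior mean of delta_j
    u_mean: np.ndarray                # polygenic / animal-model effect, len n
    mu_mean: float
    sex_effect_mean: float            # female - male contrast
    pi_mean: float
    sigma2_alpha_mean: float
    sigma2_u_mean: float
    sigma2_e_mean: float
    avg_n_snps: float
    h2_mean: float
    samples: dict = field(default_factory=dict)   # per-sample scalar traces
    alpha_chain: np.ndarray | None = None         # thinned (S, m), zeros when excluded
    n_training: int = 0

    @property
    def genetic_variance_mean(self) -> float:
        """Animal-model genetic variance (alias of the u-variance)."""
        return self.sigma2_u_mean


def sample_pi(delta: np.ndarray, rng: np.random.Generator) -> float:
    """pi | delta ~ Beta(m0 + 1, m1 + 1) under the uniform prior."""
    m1 = int(np.sum(delta))
    m0 = delta.size - m1
    return float(rng.beta(m0 + 1, m1 + 1))


def sample_scaled_inv_chi2(rng: np.random.Generator, df: float, scale_ss: float) -> float:
    """Draw from (scale_ss) / chi2_df — the scaled inverse-chi-square full
    conditional with total sum of squares ``scale_ss`` and ``df`` degrees."""
    if df <= 0:
        raise ValueError("degrees of freedom must be positive")
    return float(scale_ss / rng.chisquare(df))


def _prepare_fixed(sex: np.ndarray, train: np.ndarray) -> np.ndarray:
    """Design columns (intercept, female indicator), zeroed off-training."""
    F = np.zeros((sex.size, 2))
    F[train, 0] = 1.0
    F[train & (np.asarray(sex) == 1), 1] = 1.0
    return F


def _sweep_fixed(F, b, e, s2e, rng):
    for k in range(F.shape[1]):
        f = F[:, k]
        ff = f @ f
        if ff == 0:
            continue
        rhs = f @ e + ff * b[k]
        new = rhs / ff + rng.normal() * np.sqrt(s2e / ff)
        e += f * (b[k] - new)
        b[k] = new


def run_mcmc(y: np.ndarray, sex: np.ndarray, X: np.ndarray,
             spec: ModelSpec, ainv: np.ndarray | None = None) -> PosteriorSummary:
    """Run the marker-based Gibbs sampler.

    ``y`` has NaN for unphenotyped individuals — only phenotyped rows enter
    the likelihood; ``X`` covers all individuals. ``ainv`` (the inverse
    numerator relationship matrix over all individuals) is required when the
    spec includes a polygenic term.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X)
    n_all, m = X.shape
    if m < 1:
        raise ValueError("need at least one SNP column")
    train = ~np.isnan(y)
    n = int(train.sum())
    if n < 3:
        raise ValueError("need at least 3 phenotyped individuals")
    if spec.include_polygenic and ainv is None:
        raise ValueError("polygenic term requested but no A-inverse supplied")
    if ainv is not None and tuple(ainv.shape) != (n_all, n_all):
        raise ValueError("A-inverse dimension does not match the individual count")

    rng = np.random.default_rng(spec.seed)
    p = X[train].mean(axis=0) / 2.0
    Xw = np.where(train[:, None], X - 2.0 * p, 0.0).astype(np.float64)
    xtx = np.einsum("ij,ij->j", Xw, Xw)
    sum2pq = float(np.sum(2 * p * (1 - p)))

    y_obs = y[train]
    vp = float(np.var(y_obs, ddof=1))
    s2g_prior = spec.prior_genetic_variance if spec.prior_genetic_variance is not None \
        else 0.5 * vp
    pi0 = spec.initial_pi()
    nz_share = max(1.0 - pi0, 1.0 / m)
    s2alpha_scale = spec.prior_alpha_scale if spec.prior_alpha_scale is not None \
        else s2g_prior * (spec.nu_alpha - 2) / spec.nu_alpha / \
        max(nz_share * sum2pq, 1e-12)
    s2e_scale = spec.prior_residual_scale if spec.prior_residual_scale is not None \
        else max(vp - s2g_prior, 0.05 * vp) * (spec.nu_e - 2) / spec.nu_e
    s2u_scale = spec.prior_u_scale if spec.prior_u_scale is not None \
        else s2g_prior * (spec.nu_u - 2) / spec.nu_u

    # state
    b = np.zeros(2)
    b[0] = float(np.mean(y_obs))
    alpha = np.zeros(m)
    delta = np.zeros(m, dtype=np.int8)
    s2a_common = spec.sigma2_alpha_fixed if spec.sigma2_alpha_fixed is not None \
        else s2alpha_scale * spec.nu_alpha / max(spec.nu_alpha - 2, 0.5)
    s2a = np.full(m, s2a_common)
    s2e = spec.sigma2_e_fixed if spec.sigma2_e_fixed is not None else 0.5 * vp
    s2u = spec.sigma2_u_fixed if spec.sigma2_u_fixed is not None \
        else 0.5 * s2g_prior
    pi = pi0
    u = np.zeros(n_all)
    obs = train.astype(np.int8)
    F = _prepare_fixed(sex, train)
    e = np.where(train, y - F @ b, 0.0)

    return _gibbs_loop(y, train, obs, F, Xw, xtx, ainv, spec, rng,
                       b, alpha, delta, s2a, s2e, s2u, pi,
                       u, e, s2alpha_scale, s2e_scale, s2u_scale, n, m,
                       marker_model=True)


def run_animal_model(y: np.ndarray, sex: np.ndarray, kernel,
                     spec: ModelSpec, kernel_inverse: np.ndarray | None = None
                     ) -> PosteriorSummary:
    """Animal model y = mu 1 + W s + u + e with u ~ N(0, K sigma2_g).

    ``kernel`` is a RelationshipMatrix or square array (A for P-BLUP, G for
    G-BLUP); its posterior-mean u is the (G)EBV. ``kernel_inverse`` may be
    supplied to skip the dense inversion (e.g. Henderson's A-inverse).
    """
    K = getattr(kernel, "values", kernel)
    y = np.asarray(y, dtype=float)
    n_all = y.size
    if K.shape != (n_all, n_all):
        raise ValueError("kernel dimension does not match the individual count")
    if kernel_inverse is None:
        try:
            kernel_inverse = np.linalg.inv(K)
        except np.linalg.LinAlgError:
            kernel_inverse = np.linalg.inv(K + 1e-6 * np.eye(n_all))
    train = ~np.isnan(y)
    n = int(train.sum())
    if n < 3:
        raise ValueError("need at least 3 phenotyped individuals")

    rng = np.random.default_rng(spec.seed)
    y_obs = y[train]
    vp = float(np.var(y_obs, ddof=1))
    s2g_prior = spec.prior_genetic_variance if spec.prior_genetic_variance is not None \
        else 0.5 * vp
    s2e_scale = spec.prior_residual_scale if spec.prior_residual_scale is not None \
        else max(vp - s2g_prior, 0.05 * vp) * (spec.nu_e - 2) / spec.nu_e
    s2u_scale = spec.prior_u_scale if spec.prior_u_scale is not None \
        else s2g_prior * (spec.nu_u - 2) / spec.nu_u

    b = np.zeros(2)
    b[0] = float(np.mean(y_obs))
    u = np.zeros(n_all)
    s2e = spec.sigma2_e_fixed if spec.sigma2_e_fixed is not None else 0.5 * vp
    s2u = spec.sigma2_u_fixed if spec.sigma2_u_fixed is not None \
        else 0.5 * s2g_prior
    obs = train.astype(np.int8)
    F = _prepare_fixed(sex, train)
    e = np.where(train, y - F @ b, 0.0)
    dummyX = np.zeros((n_all, 1))
    return _gibbs_loop(y, train, obs, F, dummyX, np.zeros(1), kernel_inverse,
                       spec, rng, b, np.zeros(1), np.zeros(1, dtype=np.int8),
                       np.ones(1), s2e, s2u, 1.0, u, e,
                       1.0, s2e_scale, s2u_scale, n, 1, marker_model=False)


def _gibbs_loop(y, train, obs, F, Xw, xtx, kinv, spec, rng,
                b, alpha, delta, s2a, s2e, s2u, pi, u, e,
                s2alpha_scale, s2e_scale, s2u_scale, n, m, marker_model):
    n_all = y.size
    use_u = (not marker_model) or spec.include_polygenic
    sparse_kinv = None
    if use_u:
        import scipy.sparse as sp
        if sp.issparse(kinv):
            csr = kinv.tocsr()
            sparse_kinv = (csr.indptr.astype(np.int64),
                           csr.indices.astype(np.int64),
                           csr.data.astype(np.float64))
        else:
            kinv = np.ascontiguousarray(kinv, dtype=np.float64)
    n_keep = spec.chain_length - spec.burn_in
    sum_alpha = np.zeros(m)
    sumsq_alpha = np.zeros(m)
    sum_delta = np.zeros(m)
    sum_u = np.zeros(n_all)
    sum_b = np.zeros(2)
    traces = {k: np.empty(n_keep) for k in
              ("sigma2_alpha", "sigma2_u", "sigma2_e", "pi", "n_snps", "h2")}
    chain = np.zeros((int(np.ceil(n_keep / spec.thin)), m), dtype=np.float32) \
        if (spec.store_chain and marker_model) else None
    kept = 0

    for it in range(spec.chain_length):
        _sweep_fixed(F, b, e, s2e, rng)

        n_in = 0
        if marker_model:
            unif = rng.random(m)
            z = rng.standard_normal(m)
            n_in = sweep_loci(Xw, xtx, e, alpha, delta, s2a, s2e, pi, unif, z)
            # effect variance(s)
            if spec.sigma2_alpha_fixed is not None:
                pass
            elif spec.method == "bayesB":
                chi_in = rng.chisquare(spec.nu_alpha + 1, m)
                chi_out = rng.chisquare(spec.nu_alpha, m)
                inc = delta == 1
                s2a[inc] = (alpha[inc] ** 2 + spec.nu_alpha * s2alpha_scale) \
                    / chi_in[inc]
                s2a[~inc] = spec.nu_alpha * s2alpha_scale / chi_out[~inc]
            else:
                ss = float(np.sum(alpha[delta == 1] ** 2)) \
                    + spec.nu_alpha * s2alpha_scale
                s2a[:] = sample_scaled_inv_chi2(rng, n_in + spec.nu_alpha, ss)
            if spec.method == "bayesCpi":
                pi = sample_pi(delta, rng)

        if use_u:
            z = rng.standard_normal(n_all)
            if sparse_kinv is not None:
                indptr, indices, data = sparse_kinv
                sweep_random_effect_sparse(indptr, indices, data, u, e, obs,
                                           s2u, s2e, z)
                ss_u = quad_form_sparse(indptr, indices, data, u) \
                    + spec.nu_u * s2u_scale
            else:
                sweep_random_effect(kinv, u, e, obs, s2u, s2e, z)
                ss_u = quad_form(kinv, u) + spec.nu_u * s2u_scale
            if spec.sigma2_u_fixed is None:
                s2u = sample_scaled_inv_chi2(rng, n_all + spec.nu_u, ss_u)

        if spec.sigma2_e_fixed is None:
            ss_e = float(e @ e) + spec.nu_e * s2e_scale
            s2e = sample_scaled_inv_chi2(rng, n + spec.nu_e, ss_e)

        if not np.isfinite(s2e) or not np.isfinite(e).all():
            raise FloatingPointError(f"non-finite sampler state at iteration {it}")
        if spec.check_every and (it + 1) % spec.check_every == 0:
            fresh = np.where(train, y - F @ b - (Xw @ alpha if marker_model else 0.0)
                             - (u if use_u else 0.0), 0.0)
            drift = float(np.max(np.abs(fresh - e)))
            if drift > 1e-6:
                raise FloatingPointError(
                    f"residual identity drifted to {drift:g} at iteration {it}")
            e = fresh

        if it >= spec.burn_in:
            k = it - spec.burn_in
            sum_alpha += alpha * (delta == 1)
            sumsq_alpha += (alpha * (delta == 1)) ** 2
            sum_delta += delta
            sum_u += u
            sum_b += b
            traces["sigma2_alpha"][k] = s2a[0] if spec.method != "bayesB" \
                else float(np.mean(s2a))
            traces["sigma2_u"][k] = s2u if use_u else 0.0
            traces["sigma2_e"][k] = s2e
            traces["pi"][k] = pi
            traces["n_snps"][k] = n_in
            g = traces["sigma2_u"][k]
            traces["h2"][k] = g / (g + s2e) if use_u else np.nan
            if chain is not None and k % spec.thin == 0:
                chain[k // spec.thin] = alpha * (delta == 1)
            kept += 1

    mean_alpha = sum_alpha / kept
    sd_alpha = np.sqrt(np.maximum(sumsq_alpha / kept - mean_alpha ** 2, 0.0))
    mf = sum_delta / kept
    return PosteriorSummary(
        alpha_mean=mean_alpha, alpha_sd=sd_alpha, model_freq=mf,
        u_mean=sum_u / kept, mu_mean=float(sum_b[0] / kept),
        sex_effect_mean=float(sum_b[1] / kept),
        pi_mean=float(np.mean(traces["pi"])),
        sigma2_alpha_mean=float(np.mean(traces["sigma2_alpha"])),
        sigma2_u_mean=float(np.mean(traces["sigma2_u"])),
        sigma2_e_mean=float(np.mean(traces["sigma2_e"])),
        avg_n_snps=float(np.mean(traces["n_snps"])),
        h2_mean=float(np.nanmean(traces["h2"])) if use_u else float("nan"),
        samples=traces, alpha_chain=chain, n_training=n)


def fit_study(study, spec: ModelSpec, train_generations=None,
              kernel: str | None = None) -> PosteriorSummary:
    """Fit any supported model to a SimulatedStudy.

    ``train_generations`` restricts the likelihood to those pedigree
    generations (default: every phenotyped one). ``kernel`` selects an animal
    model: "A" (P-BLUP) or "G" (G-BLUP); otherwise the marker model in
    ``spec.method`` is run.
    """
    from .relmat import numerator_relationship, numerator_relationship_inverse, \
        genomic_relationship
    y = study.y.copy()
    if train_generations is not None:
        keep = np.isin(study.pedigree.generation, np.asarray(list(train_generations)))
        y[~keep] = np.nan
    if kernel == "A" or spec.method == "pedigree_blup":
        import scipy.sparse as sp
        K = numerator_relationship(study.pedigree)
        ainv = sp.csr_matrix(
            numerator_relationship_inverse(study.pedigree, K.inbreeding))
        return run_animal_model(y, study.pedigree.sex, K, spec, kernel_inverse=ainv)
    if kernel == "G":
        G = genomic_relationship(study.X)
        return run_animal_model(y, study.pedigree.sex, G, spec)
    ainv = None
    if spec.include_polygenic:
        import scipy.sparse as sp
        ainv = sp.csr_matrix(numerator_relationship_inverse(study.pedigree))
    return run_mcmc(y, study.pedigree.sex, study.X, spec, ainv=ainv)
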