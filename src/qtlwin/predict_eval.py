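"""GEBV computation, accuracy/bias evaluation and variance reporting.

Accuracy of prediction is measured three ways: correlation of GEBV with
phenotype divided by sqrt(h2), correlation with true breeding value, and
correlation with genotypic value; bias as the regression slope of each target
on GEBV. Heritability is estimated from the full pedigree with the Bayesian
animal model (posterior mean of Vg / (Vg + Ve)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bayesreg import ModelSpec, PosteriorSummary, run_animal_model
from .relmat import numerator_relationship, numerator_relationship_inverse


def compute_gebv(posterior: PosteriorSummary, X: np.ndarray,
                 include_polygenic: bool = True) -> np.ndarray:
    """GEBV_i = u_i + sum_j X_ij alpha_j for every genotyped individual."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != posterior.alpha_mean.size:
        raise ValueError(
            f"genotypes carry {X.shape[1]} SNPs but the posterior has "
            f"{posterior.alpha_mean.size}")
    gebv = X @ posterior.alpha_mean
    if include_polygenic and posterior.u_mean.size == X.shape[0]:
        gebv = gebv + posterior.u_mean
    return gebv


def _corr_slope(target: np.ndarray, gebv: np.ndarray) -> tuple[float, float]:
    v = float(np.var(gebv, ddof=1))
    c = float(np.cov(target, gebv, ddof=1)[0, 1])
    corr = c / np.sqrt(v * np.var(target, ddof=1))
    return corr, c / v


@dataclass
class EvalReport:
    accuracy_phenotype: float   # corr(GEBV, y) / sqrt(h2)
    corr_phenotype: float
    corr_tbv: float
    corr_genotypic: float
    slope_phenotype: float
    slope_tbv: float
    slope_genotypic: float
    h2_used: float
    h2_source: str
    n: int
    degenerate: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


def evaluate(gebv: np.ndarray, phenotypes: np.ndarray, tbv: np.ndarray,
             genotypic: np.ndarray, h2: float,
             h2_source: str = "estimated") -> EvalReport:
    """Correlations and OLS slopes of y / TBV / g on GEBV in a validation set.

    Rows with missing phenotype are dropped for the phenotype-based measures
    but kept for the truth-based ones.
    """
    gebv = np.asarray(gebv, float)
    if gebv.size < 3:
        raise ValueError("need at least 3 individuals")
    if float(np.var(gebv, ddof=1)) == 0.0:
        return EvalReport(*([float("nan")] * 7), h2, h2_source, gebv.size,
                          degenerate=True)
    y = np.asarray(phenotypes, float)
    ok = ~np.isnan(y)
    if ok.sum() >= 3:
        corr_y, slope_y = _corr_slope(y[ok], gebv[ok])
    else:
        corr_y = slope_y = float("nan")
    corr_t, slope_t = _corr_slope(np.asarray(tbv, float), gebv)
    corr_g, slope_g = _corr_slope(np.asarray(genotypic, float), gebv)
    return EvalReport(corr_y / np.sqrt(h2), corr_y, corr_t, corr_g,
                      slope_y, slope_t, slope_g, h2, h2_source, gebv.size)


def estimate_h2(y: np.ndarray, sex: np.ndarray, pedigree,
                spec: ModelSpec | None = None) -> float:
    """Pedigree animal-model heritability from all phenotyped individuals."""
    if spec is None:
        spec = ModelSpec(method="pedigree_blup", chain_length=10_000,
                         burn_in=4_000, seed=0)
    if (~np.isnan(np.asarray(y, float))).sum() < 3:
        raise ValueError("no phenotyped individuals to estimate h2 from")
    import scipy.sparse as sp
    A = numerator_relationship(pedigree)
    ainv = sp.csr_matrix(numerator_relationship_inverse(pedigree, A.inbreeding))
    post = run_animal_model(y, sex, A, spec, kernel_inverse=ainv)
    return post.h2_mean


@dataclass
class VarianceTable:
    marker_variance: float
    polygenic_variance: float
    genetic_variance: float
    residual_variance: float
    total_variance: float
    heritability: float
    avg_n_snps: float
    marker_variance_mode: str   # "posterior_mean" | "per_sample"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


def variance_table(posterior: PosteriorSummary, X: np.ndarray,
                   training_mask: np.ndarray,
                   per_sample: bool = False) -> VarianceTable:
    """Variance decomposition in the style of a genomic-prediction report.

    Marker variance is the across-individual variance of the marker part of
    GEBV in the training set — by default from posterior-mean effects, or
    (``per_sample``) averaged over the stored chain, which undoes the shrink
    of the posterior mean.
    """
    Xt = np.asarray(X, float)[np.asarray(training_mask, bool)]
    if Xt.shape[0] == 0:
        raise ValueError("training set is empty")
    if per_sample:
        if posterior.alpha_chain is None:
            raise ValueError("per-sample variance needs a stored chain "
                             "(refit with store_chain=True)")
        mv = float(np.mean([np.var(Xt @ a, ddof=1)
                            for a in posterior.alpha_chain.astype(float)]))
        mode = "per_sample"
    else:
        mv = float(np.var(Xt @ posterior.alpha_mean, ddof=1))
        mode = "posterior_mean"
    pv = posterior.sigma2_u_mean
    gv = mv + pv
    rv = posterior.sigma2_e_mean
    tot = gv + rv
    return VarianceTable(mv, pv, gv, rv, tot, gv / tot,
                         posterior.avg_n_snps, mode)
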