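"""Null distributions and chromosome-wise thresholds for the window scan.

Null datasets keep the real phenotypes but remove any LD between QTL and
SNPs in one of three ways: permuting phenotypes against genotypes (destroys
pedigree structure too), gene-dropping fresh genotypes down the real pedigree
from linkage-equilibrium founders, or doing the same from founders carrying
historical LD built by a bottlenecked Wright-Fisher simulation. Each null
dataset is refit with BayesC (pi fixed at the real-data BayesCpi posterior
mean, no polygenic term) and its window variances pooled; thresholds are
empirical upper quantiles at chromosome-wise error rates divided by the
effective number of loci Me = 2 Ne L / ln(4 Ne L).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import popsim
from .bayesreg import ModelSpec, run_mcmc
from .qtlscan import WindowScan, window_variances

STRATEGIES = ("permutation", "le_simulation", "ld_simulation")


@dataclass
class NullDataset:
    strategy: str
    X: np.ndarray
    y: np.ndarray          # always the real phenotypes (possibly permuted)
    seed: int


@dataclass
class ThresholdSet:
    me: float
    tiers: dict[str, float]              # tier name -> chromosome-wise rate
    comparison_rates: dict[str, float]   # tier name -> rate / Me
    thresholds: dict[str, float]         # tier name -> window-variance cutoff
    strategy: str
    n_null: int


def permute_null(study, seed=0) -> NullDataset:
    """Permute phenotypes against genotype rows within the training set."""
    rng = popsim._rng(seed)
    y = study.y.copy()
    train = np.flatnonzero(~np.isnan(y))
    y[train] = y[rng.permutation(train)]
    return NullDataset("permutation", study.X, y,
                       int(seed) if np.isscalar(seed) else -1)


def simulate_null_genotypes(study, mode: str = "le",
                            schedule: popsim.NeSchedule | None = None,
                            seed=0,
                            chrom_length_bp: int | None = popsim.BP_PER_MORGAN
                            ) -> NullDataset:
    """Gene-drop fresh genotypes down the real pedigree, keep real phenotypes.

    ``mode`` "le": founders in linkage equilibrium at the observed per-SNP
    allele frequencies; "ld": founders sampled from a historical
    Wright-Fisher cohort run over ``schedule`` (default: Ne 500 for 1,000
    generations, a one-generation bottleneck at 100, then growth to 1,500).
    """
    rng = popsim._rng(seed)
    ped = study.pedigree
    if mode == "le":
        pool = popsim.simulate_founders_le(
            ped.n_founders, study.gmap,
            study.X.mean(axis=0) / 2.0, rng)
    elif mode == "ld":
        schedule = schedule or popsim.NeSchedule()
        cohort = popsim.simulate_founders_ld(schedule, study.gmap, seed=rng,
                                             chrom_length_bp=chrom_length_bp)
        pool = popsim.sample_founder_pool(cohort, ped.n_founders, rng)
    else:
        raise ValueError("mode must be 'le' or 'ld'")
    Xn, _ = popsim.gene_drop(ped, pool, study.gmap, rng,
                             chrom_length_bp=chrom_length_bp)
    name = "le_simulation" if mode == "le" else "ld_simulation"
    return NullDataset(name, Xn, study.y, int(seed) if np.isscalar(seed) else -1)


def fit_null(null_dataset: NullDataset, sex: np.ndarray, gmap,
             pi_hat: float, spec: ModelSpec | None = None,
             window_size: int = 10, step: int = 1) -> WindowScan:
    """Refit the null data with BayesC (pi held at ``pi_hat``, no polygenic
    term) and scan its window variances over the phenotyped individuals."""
    if not 0.0 < pi_hat < 1.0:
        raise ValueError("pi_hat must lie in (0, 1)")
    if spec is None:
        spec = ModelSpec(method="bayesC", pi=pi_hat, chain_length=50_000,
                         burn_in=20_000, seed=null_dataset.seed)
    else:
        spec = ModelSpec(**{**vars(spec), "method": "bayesC", "pi": pi_hat,
                            "include_polygenic": False})
    post = run_mcmc(null_dataset.y, sex, null_dataset.X, spec)
    ref = ~np.isnan(null_dataset.y)
    return window_variances(post.alpha_mean, null_dataset.X[ref], gmap,
                            window_size, step)


def effective_loci(ne: float, length_morgan: float = 1.0) -> float:
    """Effective number of independent loci per chromosome,
    Me = 2 Ne L / ln(4 Ne L)."""
    if ne <= 1 or length_morgan <= 0:
        raise ValueError("need Ne > 1 and L > 0")
    x = 4.0 * ne * length_morgan
    if x <= 1.0:
        raise ValueError("4 Ne L must exceed 1")
    return 2.0 * ne * length_morgan / np.log(x)


def nearest_rank_quantile(values: np.ndarray, q: float) -> float:
    """Upper nearest-rank empirical quantile: the ceil(qN)-th order statistic."""
    v = np.sort(np.asarray(values, float))
    n = v.size
    if n == 0:
        raise ValueError("empty sample")
    k = int(np.ceil(q * n))
    return float(v[max(k, 1) - 1])


def derive_thresholds(null_scans, me: float,
                      tiers: dict[str, float] | None = None,
                      strategy: str = "") -> ThresholdSet:
    """Chromosome-wise thresholds from pooled null window variances.

    Per tier, the comparison-wise rate is alpha / Me and the threshold the
    empirical (1 - alpha/Me) nearest-rank quantile of the pooled null sample.
    """
    if tiers is None:
        tiers = {"primary": 0.10, "secondary": 0.20}
    if isinstance(null_scans, WindowScan):
        null_scans = [null_scans]
    pooled = np.concatenate([s.variance for s in null_scans])
    if pooled.size == 0:
        raise ValueError("empty null window-variance sample")
    rates, thresholds = {}, {}
    for tier, a in tiers.items():
        rate = a / me
        if rate >= 1.0:
            raise ValueError(f"comparison-wise rate {rate:g} >= 1 for tier {tier}")
        need = int(np.ceil(1.0 / rate))
        if pooled.size < need:
            raise ValueError(
                f"null sample of {pooled.size} too small for tier {tier}: "
                f"need at least {need} window variances")
        rates[tier] = rate
        thresholds[tier] = nearest_rank_quantile(pooled, 1.0 - rate)
    return ThresholdSet(me, dict(tiers), rates, thresholds, strategy,
                        int(pooled.size))
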