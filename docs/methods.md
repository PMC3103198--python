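# Methods

## Statistical model and samplers

All marker-based fits use the linear mixed mixture model
`y = μ1 + W s + u + Σ_j X_j α_j δ_j + e` over the phenotyped individuals.
Genotype columns are centered by their training-set mean (`2 p_j`), which
decorrelates SNP effects from the intercept; the GEBV and every window
variance are invariant to the centering constant. Fixed effects are
parameterised identifiably as an intercept plus a female contrast and
sampled from normal full conditionals under flat priors.

Each SNP is updated by a joint draw of `(δ_j, α_j)`: the inclusion indicator
is Bernoulli with odds equal to the prior odds `(1 − π)/π` times the
integrated likelihood ratio (computed in log space with an overflow guard),
and `α_j | δ_j = 1` is then drawn from its normal full conditional with the
residual updated incrementally. Marginalising `α_j` out of the δ-draw keeps
the chain mobile even when an effect is currently large — conditioning on
`α_j` would almost never flip its indicator.

Priors: `π ~ Uniform(0, 1)` when estimated (full conditional
`Beta(m₀ + 1, m₁ + 1)`), effect and residual variances scaled inverse
chi-square. Hyperparameter defaults: `ν_α = 4.2` with scale
`S²_α = σ̃²_g (ν_α − 2)/ν_α / ((1 − π₀) Σ_j 2 p_j (1 − p_j))`, where
`σ̃²_g` is the prior genetic variance (default: half the sample phenotypic
variance) and `π₀` the initial π; `ν_e = ν_u = 4` with scales derived from
the phenotypic-variance split. All scales are overridable
(`ModelSpec.prior_*_scale`), and any variance component can be held fixed
(`ModelSpec.sigma2_*_fixed`) — used for conjugate-oracle tests and for
model-equivalence runs at matched variances. BayesB draws a locus-specific
`σ²_{αj}` (posterior `(α_j² + ν_α S²_α)/χ²_{ν_α+1}` when included, prior
draw otherwise); the BayesC family shares one `σ²_α`.

The polygenic / animal-model effect `u` is updated by single-site Gibbs
against `K⁻¹` (K = A or G). For the pedigree kernel, `A⁻¹` is assembled
directly from Henderson's rules with inbreeding (Mendelian-sampling
variances from the tabular-method `F_i`) and stored sparse, making one sweep
O(pedigree links) rather than O(n²); dense kernels (G) use the dense sweep.
Dense-kernel single-site chains mix slowly when the kernel is nearly
singular, so G receives a ridge (10⁻⁶ by default in `genomic_relationship`;
larger values help mixing and barely move the EBVs).

The residual vector is maintained incrementally and recomputed from scratch
every 1,000 iterations; drift beyond 10⁻⁶ or any non-finite state aborts
the run with the iteration index. Chains are reproducible from a single
integer seed (one `numpy` Generator drives every draw; the numba kernels
consume pre-generated random arrays). Posterior summaries use every
post-burn-in sample; an optional thinned chain of `α δ` vectors (default
thin 10, float32) supports the per-sample window-variance statistic.
Defaults are 50,000 iterations with 20,000 burn-in; the test suite and the
acceptance script use shorter chains (stated where used) because the
posterior means they check stabilise much earlier at those problem sizes.

## Relationship matrices

`A` by the tabular method; `A⁻¹` by Henderson/Quaas (their agreement is a
test invariant). `G` by VanRaden's method 1,
`G = Z Z' / Σ 2 p_j (1 − p_j)` with observed (or supplied) frequencies.
At matched variance components (`σ²_u = σ²_α Σ 2p(1−p)`), SNP-BLUP and the
G animal model give the same GEBVs up to Monte Carlo error; the suite
asserts correlation > 0.99.

## Synthetic studies

The generator emulates a QTLMAS-style workshop population: 5 generations
(founders included) from 20 founders (5 male, 15 female), 5 chromosomes of
100 Mbp with 1 Mbp = 1 cM (so 1 Morgan each), evenly spaced SNPs (10,031 at
full scale), phenotypes on every generation but the last, additive and
residual variances 51.76 each (h² = 0.5), and a sex fixed effect (default
contrast 5 trait units — the original effect size is not documented, this
is simply a clearly nonzero value the fitted models must absorb).

Choices the workshop description leaves open, fixed here once:

* **Mating design** — per generation, 5 sires and up to 150 dams drawn from
  the previous generation, each dam mated to one random sire with a fixed
  number of offspring per dam (default 7, random sex). This reaches ~1,000
  offspring per generation at full scale while growing naturally from the
  20 founders.
* **Meiosis** — crossover count Poisson in the chromosome map length,
  positions uniform (Haldane, no interference), no mutation. Checked
  against the closed-form recombinant fraction `(1 − e^{−2d})/2`.
* **Founder haplotypes** — either linkage equilibrium (per-locus Bernoulli
  at configurable frequencies, default Uniform(0.1, 0.9)) or historical LD
  from a discrete-generation Wright–Fisher simulation over an effective-size
  schedule (default 500 for 1,000 generations, a one-generation bottleneck
  at 100, growth to 1,500 over 10 generations; pedigree founders sampled
  from the final cohort). The historical simulation runs 3× surplus
  candidate loci initialised at Uniform(0.1, 0.9), discards loci that fix
  or fall below the MAF floor, and snaps survivors to the nearest target
  map position (realized positions are reported, since post-drift survivors
  are unevenly spaced). Equilibrium LD follows Sved's
  `E[r²] ≈ 1/(1 + 4 N_e c)` at the realized distances, with a modest upward
  bias from conditioning on survival.
* **QTL** — default 30 additive QTL on SNP positions with gamma-distributed
  effect magnitudes (shape 0.42, random sign: a few large, many small) and
  random signs, rescaled so `Σ 2 p (1 − p) a² = V_g` exactly at founder
  frequencies; optionally 2 epistatic pairs (adjacent loci whose 1–1
  haplotype carries the full effect, so the pair behaves as one
  multi-allelic additive locus) and 3 paternally imprinted loci (maternal
  allele expressed only), both at the largest additive effect size.
* **True values** — the genotypic value g sums each locus's expressed
  effect (imprinted loci contribute the maternal allele only); the TBV is
  twice the expected progeny deviation given transmitted gametes, so a
  dam's imprinted-locus genotype counts fully while a sire's does not.
  With additive-only architectures TBV ≡ g.

What the generator does **not** emulate: mutation, selection or assortative
mating, sequence-level variation, interference, X chromosomes, genotyping
error or missing genotypes. Passing tests therefore demonstrate method
correctness under a neutral, randomly mating pedigree with clean data, not
robustness to real-data artefacts.

Within-pedigree realized genetic variance is slightly below the
founder-frequency target (relatives share alleles, reducing the
between-individual variance by roughly the mean pairwise relationship), and
drift moves realized frequencies; replicate-averaged phenotypic variances
are nevertheless within a few percent of `V_g + V_e`.

## QTL scan and thresholds

The scan statistic is the unbiased (n − 1) across-individual variance of
`w_il = Σ_{j∈window} X_ij α̂_j` over sliding windows (default 10 SNPs,
step 1, indexed by their first SNP, never spanning chromosomes). A 1-SNP
window reduces to `α̂_j² Var_i(X_ij)`. The per-sample variant averages the
per-MCMC-sample variances over the stored chain; by Jensen's inequality it
dominates the posterior-mean version window-by-window (asserted in tests)
and undoes some of the shrinkage of the posterior mean. It is computed via
banded genotype covariances and banded chain second moments, O(S·m·w)
instead of O(S·n·m).

Calling: windows above a tier's threshold are grouped into maximal
overlapping-or-contiguous runs. Within a run, two local maxima of the
single-SNP variance profile are distinct calls when the minimum between
them falls below `dip_fraction` (default 0.5) of the lower maximum, ties
broken leftmost; each call is positioned at its region's largest single-SNP
variance. The dip rule is this package's deterministic reading of "one
variance peak"; with LE founders the profile is spiky and
`dip_fraction=0.0` (one call per run) is more sensible — the choice is
recorded in the call output.

Null distributions use the real phenotypes with (a) permuted phenotype–
genotype pairing, (b) genotypes gene-dropped from LE founders at observed
allele frequencies, or (c) genotypes gene-dropped from historical-LD
founders. Null data are refit with BayesC, π fixed at the real-data
BayesCπ posterior mean and no polygenic term (re-estimating π on null data
drives it up and the thresholds spuriously down). Thresholds are upper
nearest-rank quantiles of the pooled genome-wide null window variances at
comparison-wise rates `α/M_e`, `α ∈ {0.10, 0.20}` chromosome-wise, with
`M_e = 2 N_e L / ln(4 N_e L)`, default `N_e = 100` (the schedule's
bottleneck — recorded in output since the choice is a convention) and
`L = 1` Morgan. Pooling genome-wide maximises the null sample; a
per-chromosome variant would only need the obvious restriction. One null
replicate per strategy is the default; `derive_thresholds` accepts several
scans and pools them.

## Evaluation

Accuracy is reported three ways: `corr(GEBV, y)/√h²` in the validation set,
`corr(GEBV, TBV)` and `corr(GEBV, g)`; bias as the OLS slope of each target
on GEBV. h² defaults to the pedigree animal-model posterior mean of
`σ²_g/(σ²_g + σ²_e)` estimated from all phenotyped generations — a Bayesian
stand-in for REML chosen to avoid external dependencies; both estimators
are consistent at these sizes, and a user-supplied h² is accepted. Note the
posterior mean of a variance ratio cannot reach 0 under a proper prior, so
null simulations recover small positive h² (~0.1 at n ≈ 1,000), shrinking
with data. The variance table reports the marker variance as the
across-individual variance of the marker part of the GEBV (posterior-mean
effects by default, per-sample on request), the polygenic and residual
posterior means, and heritability as genetic/total.

## Problem sizes

The acceptance script simulates four-generation studies with ~2,400
phenotyped individuals, 2,000 SNPs and 30 additive QTL, and runs
10,000-iteration animal-model chains (5 replicates for the variance
components, 10 generator replicates for the phenotypic variance); this
choice keeps replicate-averaged posterior means well inside the
Monte Carlo noise of the checks while completing in minutes. The test
suite uses smaller cohorts (a few hundred individuals, hundreds of SNPs)
and chains of 1,000–10,000 iterations, sized so that each check's
Monte Carlo error is several times smaller than its assertion tolerance.

## Known limitations

* Single-site updates mix slowly for dense, nearly singular G kernels;
  prefer SNP-BLUP (exactly equivalent at matched variances) at scale.
* The historical-LD founder simulation is O(generations × N × loci) in
  Python/numpy; the full default schedule (1,000 generations at Ne 500) is
  minutes of compute and is not exercised by the tests, which use shorter
  schedules with identical code paths.
* Survivor snapping in the LD simulation makes realized locus spacing
  uneven; analyses that need exactly even spacing should use LE founders.
* The epistatic-pair model is the additive-equivalent haplotype table only;
  no general epistasis.
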