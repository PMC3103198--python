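# qtlwin

Bayesian genomic prediction and window-variance QTL mapping for pedigreed
populations, with a built-in synthetic-study generator in the style of the
QTLMAS workshop datasets.

`qtlwin` is aimed at quantitative geneticists who want to (i) predict genomic
estimated breeding values (GEBVs) from genome-wide SNP panels on a known
pedigree, (ii) locate QTL from the fitted SNP effects with a sliding-window
variance statistic, and (iii) set genome-scan significance thresholds by
simulating null genotypes down the real pedigree — the situation where
ordinary phenotype permutation fails because family structure, not marker–QTL
LD, drives much of the signal.

## Model

All marker-based methods fit the mixture regression

```
y = μ1 + W s + u + Σ_j X_j α_j δ_j + e
```

where `y` are phenotypes, `s` a fixed sex effect, `u` an optional polygenic
effect with `u ~ N(0, A σ²_u)` (`A` the numerator relationship matrix),
`X_j` the 0/1/2 genotype at SNP `j` (column-centered), `α_j` its allele
substitution effect and `δ_j` a 0/1 inclusion indicator with
`P(δ_j = 0) = π`. Everything is estimated by single-site Gibbs sampling;
`δ_j` is drawn with `α_j` integrated out, which keeps the chain irreducible.
The variants are

| method      | effect variance          | π                         |
|-------------|--------------------------|---------------------------|
| BayesCπ     | common `σ²_α`            | estimated, uniform prior  |
| BayesC      | common `σ²_α`            | fixed                     |
| BayesB      | locus-specific `σ²_{αj}` | fixed                     |
| SNP-BLUP    | common `σ²_α`            | 0 (all SNPs in)           |
| P-BLUP / G-BLUP | animal model with kernel `A` or `G` (VanRaden) |  |

`GEBV_i = û_i + Σ_j X_ij α̂_j`. QTL are detected from the across-individual
variance of the GEBV of 10 consecutive SNPs ("window variance"); thresholds
come from the empirical null distribution of that statistic on datasets with
the real phenotypes but permuted or freshly simulated genotypes, at
chromosome-wise error rates `α/M_e` with `M_e = 2 N_e L / ln(4 N_e L)` the
effective number of loci.

The `popsim` module generates complete studies — multi-generation pedigree
from 20 founders, founder haplotypes in linkage equilibrium or with
historical LD from a bottlenecked Wright–Fisher simulation, gene-dropped
genotypes under Haldane recombination (1 Mbp = 1 cM), 30 additive plus
optional epistatic and paternally imprinted QTL with the additive variance
calibrated exactly, and phenotypes at h² = 0.5.

## Worked example

```python
import qtlwin as qw

cfg = qw.StudyConfig(
    pedigree=qw.PedigreeConfig(n_generations=4, n_dams=40, offspring_per_dam=5),
    n_snps=500, qtl_counts=qw.QTLCounts(10, 0, 0))
study = qw.simulate_study(cfg, seed=42)

spec = qw.ModelSpec(method="bayesCpi", chain_length=5000, burn_in=1500, seed=1)
post = qw.fit_study(study, spec, train_generations=(0, 1, 2))
print(post.pi_mean, post.avg_n_snps)          # 0.983, 7.4

gebv = qw.compute_gebv(post, study.X)
val = study.pedigree.generation == 3
rep = qw.evaluate(gebv[val], study.y[val], study.true_values.tbv[val],
                  study.true_values.genotypic_value[val], h2=0.5)
print(rep.corr_genotypic, rep.slope_genotypic)   # 0.953, 0.852
```

The fit recovers a sparse architecture (π̂ = 0.983, about 7 of 500 SNPs in
the model against 10 simulated QTL) and predicts the unphenotyped last
generation with accuracy 0.95 against the true genotypic values. Scanning
and calling QTL:

```python
ref = study.X[study.training_mask]
scan = qw.window_variances(post.alpha_mean, ref, study.gmap, window_size=10)
snp_var = qw.single_snp_variances(post.alpha_mean, ref)

nd = qw.simulate_null_genotypes(study, "le", seed=2)
null_spec = qw.ModelSpec(method="bayesC", pi=post.pi_mean,
                         chain_length=3000, burn_in=800, seed=2)
null_scan = qw.fit_null(nd, study.pedigree.sex, study.gmap, post.pi_mean,
                        null_spec)
me = qw.effective_loci(ne=100, length_morgan=1.0)
ts = qw.derive_thresholds(null_scan, me, strategy="le_simulation")
calls = qw.call_qtl(scan, snp_var, ts.thresholds, study.gmap, dip_fraction=0.0)
```

which prints three primary-tier (10% chromosome-wise) regions:

```
3 QTL regions called at the primary (10%) tier:
  chr3 @ 29.7 Mbp (peak window variance 22.63)
  chr4 @ 1.0 Mbp (peak window variance 14.61)
  chr5 @ 22.8 Mbp (peak window variance 20.66)
```

The four simulated QTL carrying more than 5% of the genetic variance sit at
chr3 17.8, chr3 29.7, chr4 1.0 and chr5 22.8 Mbp — the two chr3 QTL are
close enough that their windows merge into one region, the classic
limitation of window statistics. `dip_fraction=0.0` disables within-region
peak splitting, which is advisable when founders are in linkage equilibrium
and the single-SNP variance profile is spiky; the default (0.5) splits
regions whose profile dips below half of the lower of two peaks.

The same workflow is available from the shell:

```
qtlwin simulate --config config.yaml --out study/
qtlwin fit --study study/ --method bayesCpi --chain 50000 --burnin 20000 \
           --train-generations 1-4 --seed 1 --out fit/
qtlwin thresholds --study study/ --strategy ld --pi-hat auto --posterior fit/ \
                  --ne 100 --seed 2 --out thresholds.tsv
qtlwin scan --posterior fit/ --study study/ --thresholds thresholds.tsv --out out_
```

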