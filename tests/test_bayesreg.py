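"""Gibbs-sampler correctness: closed-form conjugate oracles, exhaustive
model-enumeration oracles, full-conditional distribution checks, calibration
and bookkeeping identities."""

import numpy as np
import pytest
from scipy import stats

import qtlwin as qw
from qtlwin import popsim
from qtlwin.bayesreg import (ModelSpec, run_mcmc, run_animal_model, sample_pi,
                             sample_scaled_inv_chi2)
from qtlwin.relmat import numerator_relationship, numerator_relationship_inverse


def _toy_data(n, m, seed, h2=0.5):
    rng = np.random.default_rng(seed)
    X = rng.integers(0, 3, size=(n, m)).astype(float)
    a = rng.normal(0, 1, m)
    g = (X - X.mean(0)) @ a
    g *= np.sqrt(h2 / max(np.var(g), 1e-12))
    y = 5.0 + g + rng.normal(0, np.sqrt(1 - h2), n)
    sex = np.zeros(n, int)      # all male: no sex contrast in the model
    return y, sex, X


class TestSpecValidation:
    def test_burn_in_must_be_shorter(self):
        with pytest.raises(ValueError, match="burn_in"):
            ModelSpec(chain_length=100, burn_in=100)

    def test_bayesb_requires_fixed_pi(self):
        with pytest.raises(ValueError, match="fixed pi"):
            ModelSpec(method="bayesB", pi="estimated")

    def test_pi_range(self):
        with pytest.raises(ValueError, match="pi"):
            ModelSpec(method="bayesC", pi=1.5)


class TestEmptyAndClosedForm:
    def test_pi_one_empty_model(self):
        y, sex, X = _toy_data(60, 10, seed=0)
        spec = ModelSpec(method="bayesC", pi=1.0, chain_length=2000,
                         burn_in=500, seed=1)
        post = run_mcmc(y, sex, X, spec)
        assert (post.model_freq == 0).all()
        assert (post.alpha_mean == 0).all()
        # residual variance concentrates on the (mean-adjusted) phenotype variance
        assert post.sigma2_e_mean == pytest.approx(np.var(y, ddof=1), rel=0.15)

    def test_single_snp_ridge_closed_form(self):
        rng = np.random.default_rng(4)
        n = 80
        X = rng.integers(0, 3, size=(n, 1)).astype(float)
        y = 2.0 + 0.8 * X[:, 0] + rng.normal(0, 1, n)
        s2a, s2e = 0.5, 1.0
        spec = ModelSpec(method="bayesC", pi=0.0, chain_length=20_000,
                         burn_in=2_000, seed=5, sigma2_alpha_fixed=s2a,
                         sigma2_e_fixed=s2e)
        post = run_mcmc(y, np.zeros(n, int), X, spec)
        xc = X[:, 0] - X[:, 0].mean()
        expected = (xc @ y) / (xc @ xc + s2e / s2a)
        assert post.alpha_mean[0] == pytest.approx(expected, abs=0.02)

    def test_two_snp_inclusion_matches_enumeration(self):
        # exhaustive oracle: enumerate the 4 delta configurations, integrate
        # alpha analytically and the flat intercept by projecting onto the
        # orthogonal complement of 1
        rng = np.random.default_rng(9)
        n = 24
        X = rng.integers(0, 3, size=(n, 2)).astype(float)
        y = 3.0 + 0.9 * X[:, 0] + rng.normal(0, 1.0, n)
        s2a, s2e, pi = 0.6, 1.0, 0.5
        Xc = X - X.mean(0)
        B = np.linalg.svd(np.eye(n) - np.ones((n, n)) / n)[0][:, :n - 1]
        ys = B.T @ y
        logp = {}
        for d0 in (0, 1):
            for d1 in (0, 1):
                cols = [j for j, d in enumerate((d0, d1)) if d]
                V = s2e * np.eye(n - 1)
                if cols:
                    Zs = B.T @ Xc[:, cols]
                    V = V + s2a * Zs @ Zs.T
                ll = stats.multivariate_normal.logpdf(ys, mean=None, cov=V)
                prior = (d0 + d1) * np.log(1 - pi) + (2 - d0 - d1) * np.log(pi)
                logp[(d0, d1)] = ll + prior
        z = np.exp(np.array(list(logp.values())) - max(logp.values()))
        probs = dict(zip(logp, z / z.sum()))
        incl0 = probs[(1, 0)] + probs[(1, 1)]
        incl1 = probs[(0, 1)] + probs[(1, 1)]
        spec = ModelSpec(method="bayesC", pi=pi, chain_length=60_000,
                         burn_in=5_000, seed=2, sigma2_alpha_fixed=s2a,
                         sigma2_e_fixed=s2e)
        post = run_mcmc(y, np.zeros(n, int), X, spec)
        assert post.model_freq[0] == pytest.approx(incl0, abs=0.03)
        assert post.model_freq[1] == pytest.approx(incl1, abs=0.03)

    def test_orthogonal_snp_rarely_included_under_strong_pi(self):
        # X_j uncorrelated with y and pi = 0.999: inclusion should be rare
        rng = np.random.default_rng(3)
        n = 200
        X = rng.integers(0, 3, size=(n, 1)).astype(float)
        y = rng.normal(0, 1, n)
        spec = ModelSpec(method="bayesC", pi=0.999, chain_length=20_000,
                         burn_in=1_000, seed=3, sigma2_alpha_fixed=0.01,
                         sigma2_e_fixed=1.0)
        post = run_mcmc(y, np.zeros(n, int), X, spec)
        assert post.model_freq[0] < 0.01


class TestFullConditionals:
    def test_pi_beta_moments(self):
        rng = np.random.default_rng(0)
        delta = np.array([1] * 3 + [0] * 7, dtype=np.int8)
        draws = np.array([sample_pi(delta, rng) for _ in range(100_000)])
        a, b = 7 + 1, 3 + 1     # Beta(m0+1, m1+1)
        assert draws.mean() == pytest.approx(a / (a + b), abs=0.005)
        assert draws.var() == pytest.approx(
            a * b / ((a + b) ** 2 * (a + b + 1)), rel=0.05)

    def test_pi_all_included(self):
        rng = np.random.default_rng(1)
        delta = np.ones(8, dtype=np.int8)
        draws = [sample_pi(delta, rng) for _ in range(50_000)]
        assert np.mean(draws) == pytest.approx(1 / 10, abs=0.005)

    def test_pi_symmetric_when_balanced(self):
        rng = np.random.default_rng(2)
        delta = np.array([1] * 5 + [0] * 5, dtype=np.int8)
        draws = np.array([sample_pi(delta, rng) for _ in range(50_000)])
        assert np.mean(draws) == pytest.approx(0.5, abs=0.01)

    def test_scaled_inv_chi2_matches_invgamma(self):
        rng = np.random.default_rng(5)
        df, ss = 7.0, 12.5
        draws = np.array([sample_scaled_inv_chi2(rng, df, ss)
                          for _ in range(20_000)])
        # scaled inv-chi2(df, ss) == InvGamma(df/2, ss/2)
        p = stats.kstest(draws, stats.invgamma(df / 2, scale=ss / 2).cdf).pvalue
        assert p > 0.01

    def test_bad_df_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            sample_scaled_inv_chi2(rng, 0.0, 1.0)


class TestPolygenic:
    def _fit_and_oracle(self, toy_pedigree, seed=6):
        ped = toy_pedigree
        rng = np.random.default_rng(seed)
        n = ped.n
        y = rng.normal(10, 2, n)
        y[7:] = np.nan          # last generation unphenotyped
        s2u, s2e = 2.0, 1.0
        X = np.zeros((n, 1))
        X[:, 0] = rng.integers(0, 3, n)
        spec = ModelSpec(method="bayesC", pi=1.0, include_polygenic=True,
                         chain_length=40_000, burn_in=4_000, seed=seed,
                         sigma2_u_fixed=s2u, sigma2_e_fixed=s2e)
        A = numerator_relationship(ped)
        ainv = numerator_relationship_inverse(ped, A.inbreeding)
        post = run_mcmc(y, ped.sex, X, spec, ainv=ainv)
        # oracle: mixed-model equations at the same fixed variances
        obs = ~np.isnan(y)
        Z = np.eye(n)[obs]
        F = np.column_stack([np.ones(obs.sum()), ped.sex[obs] == 1]).astype(float)
        lam = s2e / s2u
        top = np.hstack([F.T @ F, F.T @ Z])
        bot = np.hstack([Z.T @ F, Z.T @ Z + lam * ainv])
        lhs = np.vstack([top, bot])
        rhs = np.concatenate([F.T @ y[obs], Z.T @ y[obs]])
        sol = np.linalg.solve(lhs, rhs)
        return post, sol[2:]

    def test_matches_mme_blup(self, toy_pedigree):
        post, u_blup = self._fit_and_oracle(toy_pedigree)
        np.testing.assert_allclose(post.u_mean, u_blup, atol=0.08)

    def test_unphenotyped_get_nonzero_u_via_relatives(self, toy_pedigree):
        post, u_blup = self._fit_and_oracle(toy_pedigree)
        assert np.abs(u_blup[7:]).max() > 0.05
        assert np.abs(post.u_mean[7:]).max() > 0.05

    def test_sigma2_u_zero_shrinks_u(self, toy_pedigree):
        ped = toy_pedigree
        rng = np.random.default_rng(1)
        y = rng.normal(0, 1, ped.n)
        spec = ModelSpec(method="bayesC", pi=1.0, include_polygenic=True,
                         chain_length=3000, burn_in=500, seed=1,
                         sigma2_u_fixed=1e-8, sigma2_e_fixed=1.0)
        A = numerator_relationship(ped)
        ainv = numerator_relationship_inverse(ped, A.inbreeding)
        post = run_mcmc(y, ped.sex, rng.integers(0, 3, (ped.n, 1)).astype(float),
                        spec, ainv=ainv)
        assert np.abs(post.u_mean).max() < 1e-3


class TestAnimalModel:
    def test_matches_direct_solve_at_fixed_variances(self, toy_pedigree):
        ped = toy_pedigree
        rng = np.random.default_rng(8)
        y = rng.normal(0, 2, ped.n)
        s2u, s2e = 1.5, 1.0
        A = numerator_relationship(ped)
        spec = ModelSpec(method="pedigree_blup", chain_length=40_000,
                         burn_in=4_000, seed=8, sigma2_u_fixed=s2u,
                         sigma2_e_fixed=s2e)
        post = run_animal_model(y, ped.sex, A, spec)
        Ainv = np.linalg.inv(A.values)
        F = np.column_stack([np.ones(ped.n), ped.sex == 1]).astype(float)
        lam = s2e / s2u
        lhs = np.vstack([np.hstack([F.T @ F, F.T]),
                         np.hstack([F, np.eye(ped.n) + lam * Ainv])])
        rhs = np.concatenate([F.T @ y, y])
        u_blup = np.linalg.solve(lhs, rhs)[2:]
        np.testing.assert_allclose(post.u_mean, u_blup, atol=0.1)

    def test_vanishing_genetic_variance_zeroes_ebv(self, toy_pedigree):
        ped = toy_pedigree
        rng = np.random.default_rng(2)
        y = rng.normal(0, 1, ped.n)
        A = numerator_relationship(ped)
        spec = ModelSpec(method="pedigree_blup", chain_length=2000, burn_in=500,
                         seed=2, sigma2_u_fixed=1e-9, sigma2_e_fixed=1.0)
        post = run_animal_model(y, ped.sex, A, spec)
        assert np.abs(post.u_mean).max() < 1e-3


class TestBookkeepingAndDeterminism:
    def test_seed_reproducibility_and_mf_identity(self):
        y, sex, X = _toy_data(80, 30, seed=7)
        spec = ModelSpec(method="bayesCpi", chain_length=1500, burn_in=300,
                         seed=11)
        a = run_mcmc(y, sex, X, spec)
        b = run_mcmc(y, sex, X, spec)
        np.testing.assert_array_equal(a.alpha_mean, b.alpha_mean)
        np.testing.assert_array_equal(a.model_freq, b.model_freq)
        assert a.sigma2_e_mean == b.sigma2_e_mean
        # average number of SNPs in the model = sum of model frequencies
        assert a.avg_n_snps == pytest.approx(a.model_freq.sum(), rel=1e-12)
        c = run_mcmc(y, sex, X, ModelSpec(method="bayesCpi", chain_length=1500,
                                          burn_in=300, seed=12))
        assert (c.alpha_mean != a.alpha_mean).any()

    def test_bayesb_runs_with_locus_variances(self):
        y, sex, X = _toy_data(80, 25, seed=8)
        spec = ModelSpec(method="bayesB", pi=0.9, chain_length=1500,
                         burn_in=300, seed=1)
        post = run_mcmc(y, sex, X, spec)
        assert np.isfinite(post.alpha_mean).all()
        assert 0 <= post.model_freq.min() and post.model_freq.max() <= 1

    def test_pi_posterior_decreases_with_more_true_qtl(self):
        means = {}
        for k in (5, 50):
            vals = []
            for rep in range(3):
                cfg = qw.StudyConfig(
                    pedigree=popsim.PedigreeConfig(n_generations=3, n_dams=30,
                                                   offspring_per_dam=7),
                    n_snps=200, qtl_counts=popsim.QTLCounts(k, 0, 0))
                st = qw.simulate_study(cfg, seed=100 * k + rep)
                spec = ModelSpec(method="bayesCpi", chain_length=2500,
                                 burn_in=500, seed=rep)
                vals.append(qw.fit_study(st, spec).pi_mean)
            means[k] = np.mean(vals)
        assert means[50] < means[5]


class TestCalibration:
    def test_sbc_ranks_uniform_for_sigma2e_and_pi(self):
        # simulation-based calibration: truth drawn from the priors, data
        # simulated, sampler run; the rank of the truth among thinned
        # posterior draws must be uniform (flat-prior location parameters
        # cancel by translation invariance)
        rng = np.random.default_rng(123)
        n, m = 30, 8
        X = rng.integers(0, 3, size=(n, m)).astype(float)
        nu_e, s2e_scale = 4.0, 1.0
        s2a = 0.5
        n_reps, L = 100, 24      # ranks take 25 values -> 5 equal bins
        ranks_e, ranks_pi = [], []
        for rep in range(n_reps):
            pi_true = rng.uniform()
            delta = rng.random(m) > pi_true
            alpha = np.where(delta, rng.normal(0, np.sqrt(s2a), m), 0.0)
            s2e_true = nu_e * s2e_scale / rng.chisquare(nu_e)
            y = (X - X.mean(0)) @ alpha + rng.normal(0, np.sqrt(s2e_true), n)
            spec = ModelSpec(method="bayesCpi", chain_length=1000, burn_in=280,
                             seed=rep, sigma2_alpha_fixed=s2a, nu_e=nu_e,
                             prior_residual_scale=s2e_scale)
            post = run_mcmc(y, np.zeros(n, int), X, spec)
            th_e = post.samples["sigma2_e"][::30][:L]
            th_pi = post.samples["pi"][::30][:L]
            ranks_e.append(int(np.sum(th_e < s2e_true)))
            ranks_pi.append(int(np.sum(th_pi < pi_true)))
        for ranks in (ranks_e, ranks_pi):
            hist = np.bincount(np.array(ranks) // 5, minlength=5)
            p = stats.chisquare(hist).pvalue
            assert p > 0.01
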