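"""Numba-compiled inner loops for meiosis and single-site Gibbs sweeps.

All randomness is injected as pre-generated arrays from a numpy Generator in
the calling code, so chains are reproducible from a single seed and the
kernels stay pure functions of their inputs.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def recombine(h0, h1, pos, xpos, start):
    """Gamete from two parental haplotypes.

    ``xpos`` are sorted crossover positions (Morgan) on the chromosome,
    ``start`` the starting phase (0 -> h0). Phase flips at each crossover.
    """
    m = pos.size
    out = np.empty(m, dtype=h0.dtype)
    j = 0
    phase = start
    for i in range(m):
        while j < xpos.size and xpos[j] <= pos[i]:
            phase ^= 1
            j += 1
        out[i] = h0[i] if phase == 0 else h1[i]
    return out


@njit(cache=True)
def sweep_loci(X, xtx, e, alpha, delta, s2a, s2e, pi, unif, z):
    """One Gibbs sweep over SNP effects with variable selection.

    delta_j is drawn from its full conditional with alpha_j integrated out
    (Bernoulli with odds = prior odds x integrated likelihood ratio, computed
    in log space), then alpha_j | delta_j = 1 from its normal full
    conditional. ``s2a`` is per-locus (length m); BayesC-style samplers pass
    a constant vector. The residual ``e`` (phenotyped individuals) is updated
    in place. Returns the number of included loci.
    """
    n, m = X.shape
    n_in = 0
    for j in range(m):
        if xtx[j] == 0.0:
            delta[j] = 0
            alpha[j] = 0.0
            continue
        # rhs = X_j' (e with locus j removed from the predictor)
        rhs = 0.0
        for i in range(n):
            rhs += X[i, j] * e[i]
        if delta[j] == 1:
            rhs += xtx[j] * alpha[j]
        v = xtx[j] * s2a[j] + s2e
        log_bf = 0.5 * (np.log(s2e / v) + rhs * rhs * s2a[j] / (s2e * v))
        if pi >= 1.0:
            p1 = 0.0
        elif pi <= 0.0:
            p1 = 1.0
        else:
            log_odds = np.log((1.0 - pi) / pi) + log_bf
            if log_odds > 35.0:
                p1 = 1.0
            elif log_odds < -35.0:
                p1 = 0.0
            else:
                p1 = 1.0 / (1.0 + np.exp(-log_odds))
        old = alpha[j] if delta[j] == 1 else 0.0
        if unif[j] < p1:
            prec = xtx[j] + s2e / s2a[j]
            mean = rhs / prec
            new = mean + z[j] * np.sqrt(s2e / prec)
            delta[j] = 1
            alpha[j] = new
        else:
            delta[j] = 0
            alpha[j] = 0.0
            new = 0.0
        if new != old:
            diff = old - new
            for i in range(n):
                e[i] += X[i, j] * diff
        if delta[j] == 1:
            n_in += 1
    return n_in


@njit(cache=True)
def sweep_random_effect(Kinv, u, e, obs, s2u, s2e, z):
    """One single-site Gibbs sweep over a correlated random effect u.

    Prior u ~ N(0, K s2u) enters through rows of K^-1; individuals with
    obs[i] == 0 contribute no likelihood. ``e`` is the residual over all
    individuals (entries where obs == 0 are ignored) and is updated in place.
    """
    q = u.size
    for i in range(q):
        cross = 0.0
        for k in range(q):
            cross += Kinv[i, k] * u[k]
        cross -= Kinv[i, i] * u[i]
        prec = Kinv[i, i] / s2u
        rhs = -cross / s2u
        if obs[i] == 1:
            prec += 1.0 / s2e
            rhs += (e[i] + u[i]) / s2e
        new = rhs / prec + z[i] * np.sqrt(1.0 / prec)
        if obs[i] == 1:
            e[i] += u[i] - new
        u[i] = new


@njit(cache=True)
def sweep_random_effect_sparse(indptr, indices, data, u, e, obs, s2u, s2e, z):
    """Single-site sweep with K^-1 in CSR form (pedigree A-inverse is sparse)."""
    q = u.size
    for i in range(q):
        cross = 0.0
        diag = 0.0
        for idx in range(indptr[i], indptr[i + 1]):
            k = indices[idx]
            if k == i:
                diag = data[idx]
            else:
                cross += data[idx] * u[k]
        prec = diag / s2u
        rhs = -cross / s2u
        if obs[i] == 1:
            prec += 1.0 / s2e
            rhs += (e[i] + u[i]) / s2e
        new = rhs / prec + z[i] * np.sqrt(1.0 / prec)
        if obs[i] == 1:
            e[i] += u[i] - new
        u[i] = new


@njit(cache=True)
def quad_form_sparse(indptr, indices, data, u):
    q = u.size
    tot = 0.0
    for i in range(q):
        row = 0.0
        for idx in range(indptr[i], indptr[i + 1]):
            row += data[idx] * u[indices[idx]]
        tot += u[i] * row
    return tot


@njit(cache=True)
def quad_form(Kinv, u):
    """u' K^-1 u."""
    q = u.size
    tot = 0.0
    for i in range(q):
        row = 0.0
        for k in range(q):
            row += Kinv[i, k] * u[k]
        tot += u[i] * row
    return tot
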