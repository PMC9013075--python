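"""Independent brute-force oracles used by the test suite only.

Each oracle recomputes a quantity by a route independent of the package's
implementation: literal path enumeration and dense transition matrices for
the haplotype-copying HMM, hypergeometric enumeration for the Fisher test,
direct numerical optimisation of the logistic likelihood, and permutation
enumeration for the rank-sum test.
"""
import itertools
import math

import numpy as np
from scipy.optimize import minimize
from scipy.stats import hypergeom


def hmm_posterior_enumeration(L, hap, theta, s):
    """Genotype posteriors by literal enumeration of all state paths.

    L : (m, 3) likelihoods for one individual; hap : (H, m) panel.
    States are ordered haplotype pairs; per interval each chromosome stays
    with probability 1-s or jumps to a uniform haplotype with probability
    s.  Only feasible for (H^2)^m up to ~1e6.
    """
    H, m = hap.shape
    mu = theta + hap.astype(float) * (1 - 2 * theta)
    states = list(itertools.product(range(H), repeat=2))

    def emis_g(t, st):
        a, b = mu[st[0], t], mu[st[1], t]
        pg = np.array([(1 - a) * (1 - b), a * (1 - b) + (1 - a) * b, a * b])
        return pg * L[t]

    def trans(s1, s2):
        pj = (1 - s) + s / H if s1[0] == s2[0] else s / H
        pk = (1 - s) + s / H if s1[1] == s2[1] else s / H
        return pj * pk

    post = np.zeros((m, 3))
    total = 0.0
    for path in itertools.product(states, repeat=m):
        eg = [emis_g(t, path[t]) for t in range(m)]
        w = 1.0 / H ** 2
        for t in range(m):
            w *= eg[t].sum()
            if t:
                w *= trans(path[t - 1], path[t])
        total += w
        for t in range(m):
            post[t] += w * eg[t] / eg[t].sum()
    return post / total


def hmm_posterior_dense(L, hap, theta, s):
    """Genotype posteriors via dense (H^2 x H^2) transition matrices.

    Standard forward-backward written against the explicit state-pair
    transition matrix; independent of the package's factorised kernel.
    """
    H, m = hap.shape
    mu = theta + hap.astype(float) * (1 - 2 * theta)
    S = H * H
    pairs = [(j, k) for j in range(H) for k in range(H)]
    P1 = np.full((H, H), 0.0)
    for j in range(H):
        for k in range(H):
            P1[j, k] = ((1 - s) + s / H) if j == k else s / H
    T = np.zeros((S, S))
    for i1, (j1, k1) in enumerate(pairs):
        for i2, (j2, k2) in enumerate(pairs):
            T[i1, i2] = P1[j1, j2] * P1[k1, k2]

    def pg_mat(t):
        out = np.zeros((S, 3))
        for i, (j, k) in enumerate(pairs):
            a, b = mu[j, t], mu[k, t]
            out[i] = [(1 - a) * (1 - b), a * (1 - b) + (1 - a) * b, a * b]
        return out

    emis = [pg_mat(t) @ L[t] for t in range(m)]
    fwd = np.zeros((m, S))
    f = np.full(S, 1.0 / S) * emis[0]
    fwd[0] = f / f.sum()
    for t in range(1, m):
        f = (fwd[t - 1] @ T) * emis[t]
        fwd[t] = f / f.sum()
    bwd = np.zeros((m, S))
    bwd[m - 1] = 1.0
    for t in range(m - 2, -1, -1):
        b = T @ (emis[t + 1] * bwd[t + 1])
        bwd[t] = b / b.sum()
    post = np.zeros((m, 3))
    for t in range(m):
        w = fwd[t] * bwd[t]
        w /= w.sum()
        pg = pg_mat(t) * L[t][None, :]
        pg /= pg.sum(axis=1, keepdims=True)
        post[t] = w @ pg
    return post


def fisher_p_enumeration(a, b, c, d):
    """Two-sided Fisher p by summing hypergeometric probabilities of all
    tables with the observed margins that are no more probable."""
    r1, n = a + b, a + b + c + d
    c1 = a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    p_obs = hypergeom.pmf(a, n, c1, r1)
    total = 0.0
    for x in range(lo, hi + 1):
        px = hypergeom.pmf(x, n, c1, r1)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(1.0, total)


def logistic_loglik_optimum(y, X):
    """Maximised Bernoulli log-likelihood via scipy BFGS (with intercept)."""
    Xd = np.column_stack([np.ones(len(y)), X])

    def nll(beta):
        eta = Xd @ beta
        return np.sum(np.logaddexp(0.0, eta) - y * eta)

    best = None
    for start in (np.zeros(Xd.shape[1]),):
        res = minimize(nll, start, method="BFGS",
                       options={"gtol": 1e-10, "maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
    return -best.fun, best.x


def ranksum_p_enumeration(a, b):
    """Exact two-sided rank-sum p by enumerating all group assignments."""
    vals = np.concatenate([a, b])
    n, na = len(vals), len(a)
    ranks = np.argsort(np.argsort(vals)) + 1.0
    u_obs = ranks[:na].sum() - na * (na + 1) / 2
    mean_u = na * (len(b)) / 2
    count = 0
    total = 0
    for comb in itertools.combinations(range(n), na):
        u = ranks[list(comb)].sum() - na * (na + 1) / 2
        total += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-9:
            count += 1
    return count / total
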