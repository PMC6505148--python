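"""Shared test utilities: Monte-Carlo comparisons, joint-distribution
("getting it right") simulators, and the dense GLS oracle for the
vectorized mixed model."""

from __future__ import annotations

import numpy as np

from mtgp.bme import BMEGibbs, MatrixPriors
from mtgp.bmtme import BMTMEGibbs
from mtgp.linalg import safe_cholesky
from mtgp.samplers import (PredictorComponent, UnivariateGibbs, UnivariatePriors,
                           sample_inverse_wishart, sample_scaled_inv_chi2)
from mtgp.simulate import grm_centered, simulate_markers


def structured_grm(J: int, p: int = 600, seed: int = 0, n_families: int = None):
    """Centered GRM of a family-structured marker panel (identifiable genetics)."""
    if n_families is None:
        n_families = max(J // 10, 4)
    markers = simulate_markers(J, p, (0.1, 0.5), 0.0, seed=seed,
                               n_families=n_families, fst=0.3)
    return grm_centered(markers)


# ---------------------------------------------------------------------------
# Monte-Carlo error machinery
# ---------------------------------------------------------------------------

def iid_se(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(x.std(ddof=1) / np.sqrt(x.size))


def batch_se(x: np.ndarray, n_batches: int = 30) -> float:
    """Batch-means standard error for a (possibly autocorrelated) chain."""
    x = np.asarray(x, dtype=float)
    m = x.size // n_batches
    means = x[: m * n_batches].reshape(n_batches, m).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(n_batches))


def moment_z(forward: np.ndarray, chain: np.ndarray) -> float:
    """Max |z| comparing first and second moments of two simulators."""
    zs = []
    for f, c in ((forward, chain), (forward ** 2, chain ** 2)):
        se = np.hypot(iid_se(f), batch_se(c))
        zs.append(abs(f.mean() - c.mean()) / se)
    return max(zs)


# ---------------------------------------------------------------------------
# "getting it right" simulators (marginal- vs successive-conditional)
# ---------------------------------------------------------------------------

def gir_univariate(n_draws: int = 20000, seed: int = 0):
    """Forward vs Gibbs-stationary draws of sigma^2 for the BRR engine.

    Tiny fixed design (n=8, q=3), proper priors with finite fourth moments
    so moment comparisons have stable Monte-Carlo errors.
    """
    rng = np.random.default_rng(seed)
    n, q = 8, 3
    X = rng.standard_normal((n, q))
    pri = UnivariatePriors(df0=12.0, resid_scale=1.0, comp_scale=1.0)

    def forward(r):
        s2 = sample_scaled_inv_chi2(pri.df0, pri.resid_scale, r)
        sc = sample_scaled_inv_chi2(pri.df0, pri.comp_scale, r)
        u = np.sqrt(sc) * r.standard_normal(q)
        y = X @ u + np.sqrt(s2) * r.standard_normal(n)
        return s2, sc, u, y

    fwd = np.array([forward(rng)[0] for _ in range(n_draws)])

    s2, sc, u, y = forward(rng)
    sampler = UnivariateGibbs(y, [PredictorComponent(X, "BRR")],
                              include_intercept=False, priors=pri)
    comp = sampler.comps[0]
    sampler.sigma2, comp.var, comp.u = s2, sc, u
    comp.fitted = X @ u
    chain = np.empty(n_draws)
    for t in range(n_draws):
        sampler.step(rng)
        chain[t] = sampler.sigma2
        sampler.simulate_response(rng)
    return fwd, chain


def gir_bme(n_draws: int = 15000, seed: int = 1):
    """Forward vs Gibbs-stationary draws of (Sigma_t[0,0], Re[0,0]) for the
    multi-trait sampler at J=4, L=2, n=6 (no fixed effects)."""
    rng = np.random.default_rng(seed)
    n, J, L = 6, 4, 2
    Z1 = rng.standard_normal((n, J))
    nu = L + 10.0
    pri = MatrixPriors(nu_trait=nu, s_trait=np.eye(L), nu_res=nu, s_res=np.eye(L))

    def forward(r):
        St = sample_inverse_wishart(nu, np.eye(L), r)
        Re = sample_inverse_wishart(nu, np.eye(L), r)
        b1 = r.standard_normal((J, L)) @ safe_cholesky(St).T
        Y = Z1 @ b1 + r.standard_normal((n, L)) @ safe_cholesky(Re).T
        return St, Re, b1, Y

    fwd = np.array([[f[0][0, 0], f[1][0, 0]] for f in
                    (forward(rng) for _ in range(n_draws))])

    St, Re, b1, Y = forward(rng)
    sampler = BMEGibbs(Y, Z1, X=np.zeros((n, 0)), priors=pri)
    sampler.Sigma_t, sampler.Re, sampler.b1 = St, Re, b1
    sampler.F1 = Z1 @ b1
    chain = np.empty((n_draws, 2))
    for t in range(n_draws):
        sampler.step(rng)
        chain[t] = sampler.Sigma_t[0, 0], sampler.Re[0, 0]
        sampler.simulate_response(rng)
    return fwd, chain


def gir_bmtme(n_draws: int = 15000, seed: int = 2):
    """Forward vs Gibbs-stationary draws of (Sigma_t[0,0], Sigma_E[0,1],
    Re[1,1]) for the multi-trait multi-environment sampler at J=3, I=2, L=2."""
    rng = np.random.default_rng(seed)
    J, I, L = 3, 2, 2
    n = J * I
    Z1 = rng.standard_normal((n, J))
    Z2 = rng.standard_normal((n, I * J))
    nu_t = L + 10.0
    nu_e = I + 10.0
    pri = MatrixPriors(nu_trait=nu_t, s_trait=np.eye(L), nu_res=nu_t,
                       s_res=np.eye(L), nu_env=nu_e, s_env=np.eye(I))

    def forward(r):
        St = sample_inverse_wishart(nu_t, np.eye(L), r)
        Se = sample_inverse_wishart(nu_e, np.eye(I), r)
        Re = sample_inverse_wishart(nu_t, np.eye(L), r)
        Lt = safe_cholesky(St)
        b1 = r.standard_normal((J, L)) @ Lt.T
        LE = safe_cholesky(Se)
        z = r.standard_normal((I, J, L))
        b2 = (np.einsum("ik,kjl->ijl", LE, z) @ Lt.T).reshape(I * J, L)
        Y = Z1 @ b1 + Z2 @ b2 + r.standard_normal((n, L)) @ safe_cholesky(Re).T
        return St, Se, Re, b1, b2, Y

    fwd = np.array([[f[0][0, 0], f[1][0, 1], f[2][1, 1]] for f in
                    (forward(rng) for _ in range(n_draws))])

    St, Se, Re, b1, b2, Y = forward(rng)
    sampler = BMTMEGibbs(Y, np.zeros((n, 0)), Z1, Z2, priors=pri, n_env=I)
    sampler.Sigma_t, sampler.Sigma_e, sampler.Re = St, Se, Re
    sampler.b1, sampler.b2 = b1, b2
    sampler.F1, sampler.F2 = Z1 @ b1, Z2 @ b2
    chain = np.empty((n_draws, 3))
    for t in range(n_draws):
        sampler.step(rng)
        chain[t] = (sampler.Sigma_t[0, 0], sampler.Sigma_e[0, 1], sampler.Re[1, 1])
        sampler.simulate_response(rng)
    return fwd, chain


# ---------------------------------------------------------------------------
# dense GLS oracle for the vectorized mixed model
# ---------------------------------------------------------------------------

def gls_oracle(Y, X, designs, prior_precisions, Re):
    """Posterior mean of (beta, effects...) by one dense solve.

    vec(Y) = (I_L (x) X) vec(beta) + sum_c (I_L (x) Z_c) vec(b_c) + e,
    e ~ N(0, Re (x) I_n); flat prior on beta, Gaussian priors on the effects
    with the given vec-scale precisions.  Returns matrices in original shape.
    """
    Y = np.asarray(Y, float)
    n, L = Y.shape
    IL = np.eye(L)
    blocks = [np.kron(IL, X)] + [np.kron(IL, Z) for Z in designs]
    D = np.hstack(blocks)
    Rinv = np.kron(np.linalg.inv(Re), np.eye(n))
    P = D.T @ Rinv @ D
    off = X.shape[1] * L
    for Z, Pr in zip(designs, prior_precisions):
        q = Z.shape[1] * L
        P[off:off + q, off:off + q] += Pr
        off += q
    sol = np.linalg.solve(P, D.T @ Rinv @ Y.reshape(-1, order="F"))
    out = []
    off = 0
    for M in [X] + list(designs):
        q = M.shape[1]
        out.append(sol[off:off + q * L].reshape(q, L, order="F"))
        off += q * L
    return out
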