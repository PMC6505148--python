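"""Random-sampling primitives and the univariate Bayesian regression engine.

This module provides

* matrix-variate normal and inverse-Wishart draws (the conjugate building
  blocks of all model fits),
* blocked matrix-normal effect updates shared by the multi-trait samplers
  (:mod:`mtgp.bme`, :mod:`mtgp.bmtme`), and
* a univariate Gibbs engine (:func:`fit_univariate`) implementing Bayesian
  ridge regression (BRR) and BayesB marker-effect priors, used by the GBLUP
  stage-1 fits and the stacking stage-2 meta-models.

All randomness flows through a single ``numpy.random.Generator``; identical
seeds give bitwise-identical chains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy import stats

from .errors import DataValidationError
from .linalg import safe_cholesky

__all__ = [
    "ChainSettings",
    "PredictorComponent",
    "UnivariatePriors",
    "UnivariateFit",
    "sample_matrix_normal",
    "sample_inverse_wishart",
    "sample_scaled_inv_chi2",
    "fit_univariate",
    "UnivariateGibbs",
]

IMPLEMENTED_MODELS = ("BRR", "BayesB")
KNOWN_MODELS = ("BRR", "BayesA", "BayesB", "BayesC", "BL")


@dataclass(frozen=True)
class ChainSettings:
    """MCMC run configuration.

    ``block_size`` controls the row-block partition used when sampling the
    matrix-variate line and line-by-environment effects; values of at least
    50 but less than 1000 are accepted.
    """

    n_iter: int
    burn_in: int
    thin: int = 2
    block_size: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.n_iter <= 0:
            raise DataValidationError("n_iter must be positive")
        if not (0 <= self.burn_in < self.n_iter):
            raise DataValidationError("burn_in must satisfy 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise DataValidationError("thin must be a positive integer")
        if not (50 <= self.block_size < 1000):
            raise DataValidationError(
                f"block_size must be at least 50 and less than 1000 (got {self.block_size})"
            )
        if self.n_retained < 10:
            raise DataValidationError(
                "(n_iter - burn_in) / thin must allow at least 10 retained samples"
            )

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class PredictorComponent:
    """One term of a univariate linear predictor: a design matrix plus prior."""

    design: np.ndarray
    model_label: str = "BRR"
    name: str = ""

    def __post_init__(self):
        self.design = np.atleast_2d(np.asarray(self.design, dtype=float))
        if self.model_label not in KNOWN_MODELS:
            raise DataValidationError(
                f"unknown model label {self.model_label!r}; known: {KNOWN_MODELS}"
            )


@dataclass
class UnivariatePriors:
    """Hyperpriors of the univariate engine.

    Variance components carry scaled-inverse-chi-square priors with ``df0``
    degrees of freedom.  When the scale fields are ``None`` they are set so
    the prior mode equals half the sample variance of the observed response,
    split equally across components (a standard weakly informative
    genomic-selection default).  BayesB places a Beta(p0*pi0, p0*(1-pi0))
    prior on the exclusion probability pi and a scaled-t slab (``slab_df``)
    on included effects.
    """

    df0: float = 5.0
    resid_scale: Optional[float] = None
    comp_scale: Optional[float] = None
    pi0: float = 0.5
    p0: float = 10.0
    slab_df: float = 5.0
    slab_scale: Optional[float] = None


@dataclass
class UnivariateFit:
    intercept: float
    effects: List[np.ndarray]
    sigma2: float
    component_variances: List[float]
    yhat: np.ndarray
    missing: np.ndarray
    n_retained: int

    @property
    def predictions(self) -> np.ndarray:
        """Posterior-mean predictions at the missing/masked positions."""
        return self.yhat[self.missing]


# ---------------------------------------------------------------------------
# distributional primitives
# ---------------------------------------------------------------------------

def sample_matrix_normal(M: np.ndarray, U: np.ndarray, V: np.ndarray,
                         rng: np.random.Generator) -> np.ndarray:
    """Draw from MN(M, U, V): ``M + L_U Z L_V'`` with Z i.i.d. standard normal.

    ``vec`` of the draw has covariance ``V (x) U``.  U and V may be PSD
    (including zero), in which case the degenerate directions are exact.
    """
    M = np.asarray(M, dtype=float)
    n, p = M.shape
    U = np.asarray(U, dtype=float)
    V = np.asarray(V, dtype=float)
    if U.shape != (n, n) or V.shape != (p, p):
        raise DataValidationError(
            f"covariance shapes {U.shape}/{V.shape} do not match location {M.shape}"
        )
    Lu = safe_cholesky(U)
    Lv = safe_cholesky(V)
    return M + Lu @ rng.standard_normal((n, p)) @ Lv.T


def sample_inverse_wishart(df: float, scale: np.ndarray,
                           rng: np.random.Generator) -> np.ndarray:
    """Draw from the inverse-Wishart(df, scale) distribution (scale = PD matrix)."""
    scale = np.atleast_2d(np.asarray(scale, dtype=float))
    dim = scale.shape[0]
    if df <= dim - 1:
        raise DataValidationError(f"inverse-Wishart df must exceed dim - 1 = {dim - 1}")
    try:
        np.linalg.cholesky(scale)
    except np.linalg.LinAlgError:
        raise DataValidationError("inverse-Wishart scale matrix must be positive definite")
    draw = stats.invwishart.rvs(df=df, scale=scale, random_state=rng)
    return np.atleast_2d(draw)


def sample_scaled_inv_chi2(df: float, scale: float, rng: np.random.Generator) -> float:
    """Draw sigma^2 ~ Scale-inv-chi2(df, scale), i.e. df*scale / chi2_df."""
    return df * scale / rng.chisquare(df)


# ---------------------------------------------------------------------------
# blocked matrix-normal effect update (shared by the multi-trait samplers)
# ---------------------------------------------------------------------------

@dataclass
class BlockPlan:
    """Precomputed quantities for one row block of a matrix-variate effect."""

    idx: np.ndarray        # effect-row indices of this block
    Z: np.ndarray          # n x b design columns
    Q: np.ndarray          # eigenvectors of Z'Z
    d: np.ndarray          # eigenvalues of Z'Z
    ZQ: np.ndarray         # Z @ Q


def plan_blocks(Z: np.ndarray, block_size: int,
                groups: Optional[Sequence[np.ndarray]] = None) -> List[BlockPlan]:
    """Partition the columns of Z into row blocks of the effect matrix.

    ``groups`` restricts blocks to lie within given column groups (used so
    interaction-effect blocks never straddle environments, which keeps the
    conditional prior of a block isotropic).
    """
    q = Z.shape[1]
    if groups is None:
        groups = [np.arange(q)]
    plans: List[BlockPlan] = []
    for grp in groups:
        for start in range(0, len(grp), block_size):
            idx = np.asarray(grp[start:start + block_size])
            Zb = Z[:, idx]
            d, Q = np.linalg.eigh(Zb.T @ Zb)
            plans.append(BlockPlan(idx=idx, Z=Zb, Q=Q, d=np.clip(d, 0.0, None), ZQ=Zb @ Q))
    return plans


def sample_effect_block(plan: BlockPlan, resid: np.ndarray, sigma_inv: np.ndarray,
                        re_inv: np.ndarray, s_prior: float,
                        prior_mean: Optional[np.ndarray],
                        rng: np.random.Generator) -> np.ndarray:
    """Draw a b x L effect block from its matrix-normal full conditional.

    Prior: MN(prior_mean, (1/s_prior) I_b, Sigma); likelihood
    ``resid = Z_b @ B + E`` with E ~ MN(0, I_n, Re).  Rotating rows into the
    eigenbasis of Z_b'Z_b decouples them, leaving one L-dimensional
    multivariate-normal draw per row with precision
    ``s_prior * Sigma^-1 + d_j * Re^-1``.
    """
    b = len(plan.idx)
    L = re_inv.shape[0]
    rhs = plan.ZQ.T @ resid @ re_inv                       # b x L
    if prior_mean is not None:
        rhs += s_prior * (plan.Q.T @ prior_mean) @ sigma_inv
    P = s_prior * sigma_inv[None, :, :] + plan.d[:, None, None] * re_inv[None, :, :]
    Lp = np.linalg.cholesky(P)
    mean = np.linalg.solve(P, rhs[:, :, None])
    z = rng.standard_normal((b, L, 1))
    c = mean + np.linalg.solve(np.transpose(Lp, (0, 2, 1)), z)
    return plan.Q @ c[:, :, 0]


# ---------------------------------------------------------------------------
# univariate Gibbs engine
# ---------------------------------------------------------------------------

class _BRRState:
    def __init__(self, X: np.ndarray, scale0: float):
        self.X = X
        self.q = X.shape[1]
        d, Q = np.linalg.eigh(X.T @ X)
        self.d = np.clip(d, 0.0, None)
        self.Q = Q
        self.XQ = X @ Q
        self.u = np.zeros(self.q)
        self.scale0 = scale0
        self.var = scale0
        self.fitted = np.zeros(X.shape[0])


class _BayesBState:
    def __init__(self, X: np.ndarray, pi0: float, slab_scale: float):
        self.X = X
        self.q = X.shape[1]
        self.colsq = np.einsum("ij,ij->j", X, X)
        self.u = np.zeros(self.q)
        self.delta = np.ones(self.q, dtype=bool)
        self.var_k = np.full(self.q, slab_scale)
        self.pi = pi0
        self.slab_scale = slab_scale
        self.fitted = np.zeros(X.shape[0])


class UnivariateGibbs:
    """Gibbs sampler for ``y = mu + sum_c X_c u_c + e`` with conjugate updates.

    Missing entries of ``y`` are sampled from their predictive distribution
    each iteration (data augmentation), which doubles as the testing-set
    prediction mechanism.  The object exposes :meth:`step` (one full sweep)
    and mutable state so that joint-distribution correctness tests can drive
    the transition kernel directly.
    """

    def __init__(self, y: np.ndarray, components: Sequence[PredictorComponent],
                 *, include_intercept: bool = True,
                 priors: Optional[UnivariatePriors] = None,
                 fixed_sigma2: Optional[float] = None,
                 fixed_component_variances: Optional[Sequence[float]] = None):
        y = np.asarray(y, dtype=float).ravel()
        self.n = y.size
        self.missing = np.isnan(y)
        n_obs = int((~self.missing).sum())
        if n_obs == 0:
            raise DataValidationError("response is entirely missing")
        if n_obs < 3:
            raise DataValidationError("at least 3 observed response values are required")
        if not components:
            raise DataValidationError("at least one predictor component is required")
        for c in components:
            if c.design.shape[0] != self.n:
                raise DataValidationError(
                    f"component {c.name or c.model_label}: {c.design.shape[0]} rows "
                    f"for a response of length {self.n}"
                )
            if c.model_label not in IMPLEMENTED_MODELS:
                raise NotImplementedError(
                    f"model {c.model_label!r} is not implemented; "
                    f"available models: {', '.join(IMPLEMENTED_MODELS)}"
                )
        self.priors = priors or UnivariatePriors()
        pr = self.priors
        var_y = float(np.var(y[~self.missing], ddof=1)) if n_obs > 1 else 1.0
        var_y = max(var_y, 1e-12)
        ncomp = len(components)
        # prior mode m of Scale-inv-chi2(df, s) is df*s/(df+2) => s = m*(df+2)/df
        self.s0_resid = (pr.resid_scale if pr.resid_scale is not None
                         else 0.5 * var_y * (pr.df0 + 2.0) / pr.df0)
        s0_comp = (pr.comp_scale if pr.comp_scale is not None
                   else 0.5 * var_y / ncomp * (pr.df0 + 2.0) / pr.df0)

        self.include_intercept = include_intercept
        self.fixed_sigma2 = fixed_sigma2
        self.fixed_component_variances = fixed_component_variances

        self.comps: List[object] = []
        for c in components:
            if c.model_label == "BRR":
                self.comps.append(_BRRState(c.design, s0_comp))
            else:  # BayesB
                # sum of mean-squared column scales; the slab prior mode is set
                # so the expected variance contributed by included effects is
                # the component's share of 0.5 * var(y)
                sum_msx = float(np.sum(np.mean(c.design ** 2, axis=0)))
                if pr.slab_scale is not None:
                    slab = pr.slab_scale
                else:
                    mode = (0.5 * var_y / ncomp) / max((1.0 - pr.pi0) * sum_msx, 1e-12)
                    slab = mode * (pr.slab_df + 2.0) / pr.slab_df
                self.comps.append(_BayesBState(c.design, pr.pi0, slab))

        self.mu = float(np.mean(y[~self.missing])) if include_intercept else 0.0
        self.sigma2 = fixed_sigma2 if fixed_sigma2 is not None else max(0.5 * var_y, 1e-12)
        self.y = y.copy()
        self.y[self.missing] = float(np.mean(y[~self.missing]))

    # -- helpers -------------------------------------------------------------
    def linear_predictor(self) -> np.ndarray:
        f = np.full(self.n, self.mu)
        for comp in self.comps:
            f += comp.fitted
        return f

    def set_response(self, y: np.ndarray) -> None:
        """Replace the (fully observed) response; used by simulator-based tests."""
        y = np.asarray(y, dtype=float).ravel()
        self.y = y.copy()
        self.missing = np.zeros(self.n, dtype=bool)

    def simulate_response(self, rng: np.random.Generator) -> np.ndarray:
        """Draw y from the likelihood at the current state and install it."""
        y = self.linear_predictor() + math.sqrt(self.sigma2) * rng.standard_normal(self.n)
        self.set_response(y)
        return y

    # -- one Gibbs sweep -----------------------------------------------------
    def step(self, rng: np.random.Generator) -> None:
        pr = self.priors
        fitted = self.linear_predictor()
        if self.missing.any():
            nmiss = int(self.missing.sum())
            self.y[self.missing] = (fitted[self.missing]
                                    + math.sqrt(self.sigma2) * rng.standard_normal(nmiss))
        if self.include_intercept:
            r = self.y - (fitted - self.mu)
            self.mu = rng.normal(float(np.mean(r)), math.sqrt(self.sigma2 / self.n))
            fitted = self.linear_predictor()

        for ci, comp in enumerate(self.comps):
            resid = self.y - fitted + comp.fitted
            if isinstance(comp, _BRRState):
                rhs = comp.XQ.T @ resid / self.sigma2
                prec = comp.d / self.sigma2 + 1.0 / comp.var
                mean = rhs / prec
                cvec = mean + rng.standard_normal(comp.q) / np.sqrt(prec)
                comp.u = comp.Q @ cvec
                comp.fitted = comp.XQ @ cvec
                if self.fixed_component_variances is not None:
                    comp.var = float(self.fixed_component_variances[ci])
                else:
                    ssq = float(comp.u @ comp.u)
                    comp.var = (pr.df0 * comp.scale0 + ssq) / rng.chisquare(pr.df0 + comp.q)
            else:
                self._step_bayesb(comp, resid, rng)
            fitted = self.linear_predictor()

        if self.fixed_sigma2 is None:
            e = self.y - fitted
            self.sigma2 = ((pr.df0 * self.s0_resid + float(e @ e))
                           / rng.chisquare(pr.df0 + self.n))

    def _step_bayesb(self, comp: _BayesBState, resid: np.ndarray,
                     rng: np.random.Generator) -> None:
        """Single-site spike-and-slab update for a BayesB component."""
        pr = self.priors
        # resid excludes this component entirely; r tracks the residual with
        # all of this component's effects subtracted, effect k added back in turn
        r = resid - comp.fitted
        for k in range(comp.q):
            if comp.u[k] != 0.0:
                r += comp.X[:, k] * comp.u[k]
            xtx = comp.colsq[k]
            xtr = float(comp.X[:, k] @ r)
            prec = xtx / self.sigma2 + 1.0 / comp.var_k[k]
            m = (xtr / self.sigma2) / prec
            # log Bayes factor inclusion vs exclusion
            log_bf = -0.5 * math.log(comp.var_k[k] * prec) + 0.5 * m * m * prec
            p_incl = 1.0 - comp.pi
            with np.errstate(over="ignore"):
                odds = (p_incl / max(comp.pi, 1e-300)) * math.exp(min(log_bf, 700.0))
            prob = odds / (1.0 + odds)
            if rng.random() < prob:
                comp.delta[k] = True
                comp.u[k] = m + rng.standard_normal() / math.sqrt(prec)
                r -= comp.X[:, k] * comp.u[k]
            else:
                comp.delta[k] = False
                comp.u[k] = 0.0
            # per-effect slab variance (prior draw when excluded)
            ssq = comp.u[k] ** 2
            dfk = pr.slab_df + (1.0 if comp.delta[k] else 0.0)
            comp.var_k[k] = (pr.slab_df * comp.slab_scale + ssq) / rng.chisquare(dfk)
        n_excl = int((~comp.delta).sum())
        comp.pi = rng.beta(pr.p0 * pr.pi0 + n_excl,
                           pr.p0 * (1.0 - pr.pi0) + comp.q - n_excl)
        comp.fitted = comp.X @ comp.u


def fit_univariate(y: np.ndarray, components: Sequence[PredictorComponent],
                   settings: ChainSettings, *, include_intercept: bool = True,
                   priors: Optional[UnivariatePriors] = None,
                   fixed_sigma2: Optional[float] = None,
                   fixed_component_variances: Optional[Sequence[float]] = None,
                   rng: Optional[np.random.Generator] = None) -> UnivariateFit:
    """Fit the univariate Bayesian regression by Gibbs sampling.

    Posterior means are computed over retained (post burn-in, thinned)
    samples.  Missing values of ``y`` are treated as testing cells: they are
    augmented during sampling, and the fitted values at those positions are
    the model's predictions.
    """
    sampler = UnivariateGibbs(y, components, include_intercept=include_intercept,
                              priors=priors, fixed_sigma2=fixed_sigma2,
                              fixed_component_variances=fixed_component_variances)
    if rng is None:
        rng = np.random.default_rng(settings.seed)
    nret = 0
    mu_sum = 0.0
    sigma2_sum = 0.0
    u_sums = [np.zeros(c.q) for c in sampler.comps]
    var_sums = [0.0 for _ in sampler.comps]
    for it in range(1, settings.n_iter + 1):
        sampler.step(rng)
        if it > settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
            nret += 1
            mu_sum += sampler.mu
            sigma2_sum += sampler.sigma2
            for ci, comp in enumerate(sampler.comps):
                u_sums[ci] += comp.u
                var_sums[ci] += comp.var if isinstance(comp, _BRRState) else float(
                    np.mean(comp.var_k))
    mu_mean = mu_sum / nret
    effects = [s / nret for s in u_sums]
    yhat = np.full(sampler.n, mu_mean)
    for ci, comp in enumerate(sampler.comps):
        yhat += comp.X @ effects[ci]
    return UnivariateFit(
        intercept=mu_mean,
        effects=effects,
        sigma2=sigma2_sum / nret,
        component_variances=[v / nret for v in var_sums],
        yhat=yhat,
        missing=sampler.missing.copy(),
        n_retained=nret,
    )
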