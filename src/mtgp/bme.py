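"""Bayesian multi-trait (single- or pooled-environment) model.

Fits ``Y = X beta + Z1 b1 + E`` with

* ``b1 ~ MN(0, I_J, Sigma_t)`` — whitened line effects whose column
  covariance ``Sigma_t`` is the unstructured genetic (co)variance between
  traits (the design Z1 = ZG @ chol(G) carries the genomic relationship),
* ``E ~ MN(0, I_n, Re)`` — unstructured residual (co)variance between traits,

by blocked Gibbs sampling with matrix-normal effect updates and
inverse-Wishart covariance updates.  Cells named in a testing set are masked
before fitting and predicted by data augmentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from ._masking import augment_masked, testing_mask
from .errors import DataValidationError
from .linalg import safe_cholesky
from .samplers import (ChainSettings, plan_blocks, sample_effect_block,
                       sample_inverse_wishart)

__all__ = ["MatrixPriors", "BMEFit", "BMEGibbs", "fit_bme"]


@dataclass
class MatrixPriors:
    """Inverse-Wishart hyperpriors for the covariance matrices.

    Defaults (resolved at fit time): df = dim + 2 and identity scale for the
    trait-genetic (Sigma_t), residual (Re) and environment (Sigma_E)
    covariances — proper and weakly informative at toy sizes.
    """

    nu_trait: Optional[float] = None
    s_trait: Optional[np.ndarray] = None
    nu_res: Optional[float] = None
    s_res: Optional[np.ndarray] = None
    nu_env: Optional[float] = None
    s_env: Optional[np.ndarray] = None

    def resolve(self, L: int, I: Optional[int] = None):
        nu_t = self.nu_trait if self.nu_trait is not None else L + 2.0
        S_t = np.asarray(self.s_trait, float) if self.s_trait is not None else np.eye(L)
        nu_r = self.nu_res if self.nu_res is not None else L + 2.0
        S_r = np.asarray(self.s_res, float) if self.s_res is not None else np.eye(L)
        if I is None:
            return nu_t, S_t, nu_r, S_r
        nu_e = self.nu_env if self.nu_env is not None else I + 2.0
        S_e = np.asarray(self.s_env, float) if self.s_env is not None else np.eye(I)
        return nu_t, S_t, nu_r, S_r, nu_e, S_e


@dataclass
class BMEFit:
    """Posterior summaries of a multi-trait fit."""

    Y: np.ndarray
    yHat: np.ndarray
    SD_yHat: np.ndarray
    beta: np.ndarray
    SD_beta: np.ndarray
    b1: np.ndarray
    SD_b1: np.ndarray
    varTrait: np.ndarray
    SD_varTrait: np.ndarray
    vare: np.ndarray
    SD_vare: np.ndarray
    dfe: float
    Se: np.ndarray
    NAvalues: List[Tuple[int, int]]
    n_iter: int
    burn_in: int
    thin: int


class _Accumulator:
    """Running mean/SD over retained posterior draws."""

    def __init__(self):
        self.n = 0
        self.sums = {}
        self.sqs = {}

    def add(self, **arrays):
        self.n += 1
        for k, v in arrays.items():
            v = np.asarray(v, dtype=float)
            if k not in self.sums:
                self.sums[k] = np.zeros_like(v)
                self.sqs[k] = np.zeros_like(v)
            self.sums[k] += v
            self.sqs[k] += v * v

    def mean(self, k):
        return self.sums[k] / self.n

    def sd(self, k):
        m = self.mean(k)
        var = np.maximum(self.sqs[k] / self.n - m * m, 0.0)
        return np.sqrt(var)


class BMEGibbs:
    """One-sweep Gibbs transition kernel for the multi-trait model.

    Exposed as a class (rather than only through :func:`fit_bme`) so that
    joint-distribution correctness tests can alternate :meth:`step` with
    :meth:`simulate_response`.
    """

    def __init__(self, Y: np.ndarray, Z1: np.ndarray, *,
                 X: Optional[np.ndarray] = None, block_size: int = 50,
                 priors: Optional[MatrixPriors] = None, testing_set=None,
                 fix_sigma_t: Optional[np.ndarray] = None,
                 fix_re: Optional[np.ndarray] = None):
        Y = np.asarray(Y, dtype=float)
        if Y.ndim != 2:
            raise DataValidationError("Y must be an n x L matrix")
        n, L = Y.shape
        if L < 2:
            raise DataValidationError(
                "the multi-trait model requires at least 2 traits; "
                "use the univariate engine (fit_univariate) for a single trait"
            )
        Z1 = np.asarray(Z1, dtype=float)
        if Z1.shape[0] != n:
            raise DataValidationError(f"Z1 has {Z1.shape[0]} rows for {n} records")
        self.n, self.L, self.J = n, L, Z1.shape[1]
        self.Z1 = Z1
        self.X = np.ones((n, 1)) if X is None else np.asarray(X, dtype=float)
        if self.X.shape[0] != n:
            raise DataValidationError("X row count does not match Y")

        nu_t, S_t, nu_r, S_r = (priors or MatrixPriors()).resolve(L)
        self.nu_t, self.S_t, self.nu_r, self.S_r = nu_t, S_t, nu_r, S_r
        self.fix_sigma_t = None if fix_sigma_t is None else np.asarray(fix_sigma_t, float)
        self.fix_re = None if fix_re is None else np.asarray(fix_re, float)

        self.mask = testing_mask(testing_set, n, L) | np.isnan(Y)
        if self.mask.all(axis=0).any():
            raise DataValidationError("a trait has no observed (training) cells")
        self.Y_input = Y.copy()
        self.Y = Y.copy()
        col_means = np.array([np.nanmean(np.where(self.mask[:, l], np.nan, Y[:, l]))
                              for l in range(L)])
        for l in range(L):
            self.Y[self.mask[:, l], l] = col_means[l]

        # fixed-effect solve pieces (skipped when X has no columns)
        if self.X.shape[1] > 0:
            XtX = self.X.T @ self.X
            self.XtX_inv = np.linalg.inv(XtX)
            self.Lxx = safe_cholesky(self.XtX_inv)
        self.z1_plans = plan_blocks(Z1, block_size)

        # state
        self.beta = np.zeros((self.X.shape[1], L))
        if self.X.shape[1] > 0:
            self.beta = self.XtX_inv @ (self.X.T @ self.Y)
        self.b1 = np.zeros((self.J, L))
        obs_var = np.array([max(np.var(self.Y[:, l]), 1e-8) for l in range(L)])
        self.Sigma_t = (self.fix_sigma_t if self.fix_sigma_t is not None
                        else np.diag(obs_var / 2.0))
        self.Re = self.fix_re if self.fix_re is not None else np.diag(obs_var / 2.0)
        self.F1 = Z1 @ self.b1
        self.pred = self.Y.copy()

    # -- simulator hooks -------------------------------------------------
    def location(self) -> np.ndarray:
        XB = self.X @ self.beta if self.X.shape[1] else 0.0
        return XB + self.F1

    def set_response(self, Y: np.ndarray) -> None:
        self.Y = np.asarray(Y, dtype=float).copy()
        self.mask = np.zeros((self.n, self.L), dtype=bool)

    def simulate_response(self, rng: np.random.Generator) -> np.ndarray:
        E = rng.standard_normal((self.n, self.L)) @ safe_cholesky(self.Re).T
        Y = self.location() + E
        self.set_response(Y)
        return Y

    # -- one sweep --------------------------------------------------------
    def step(self, rng: np.random.Generator) -> None:
        Re_inv = np.linalg.inv(self.Re)
        St_inv = np.linalg.inv(self.Sigma_t)

        # (1) trait intercepts / fixed effects, flat prior
        if self.X.shape[1] > 0:
            E = self.Y - self.F1
            Bhat = self.XtX_inv @ (self.X.T @ E)
            Lre = safe_cholesky(self.Re)
            self.beta = Bhat + self.Lxx @ rng.standard_normal(self.beta.shape) @ Lre.T
        XB = self.X @ self.beta if self.X.shape[1] else np.zeros((self.n, self.L))

        # (2) line effects b1, row blocks
        R1 = self.Y - XB
        for plan in self.z1_plans:
            resid = R1 - self.F1 + plan.Z @ self.b1[plan.idx]
            new = sample_effect_block(plan, resid, St_inv, Re_inv, 1.0, None, rng)
            self.F1 += plan.Z @ (new - self.b1[plan.idx])
            self.b1[plan.idx] = new

        # (3) trait genetic covariance
        if self.fix_sigma_t is None:
            self.Sigma_t = sample_inverse_wishart(
                self.nu_t + self.J, self.S_t + self.b1.T @ self.b1, rng)

        # (4) residual covariance
        E = self.Y - XB - self.F1
        self._Se_update = self.S_r + E.T @ E
        if self.fix_re is None:
            self.Re = sample_inverse_wishart(self.nu_r + self.n, self._Se_update, rng)

        # (5) masked-cell augmentation and per-iteration predictive surface
        mu = XB + self.F1
        self.pred = augment_masked(mu, self.Y, self.mask, self.Re, rng)


def fit_bme(Y: np.ndarray, Z1: np.ndarray, settings: ChainSettings,
            testing_set=None, *, X: Optional[np.ndarray] = None,
            priors: Optional[MatrixPriors] = None,
            fix_sigma_t: Optional[np.ndarray] = None,
            fix_re: Optional[np.ndarray] = None,
            rng: Optional[np.random.Generator] = None) -> BMEFit:
    """Fit the multi-trait model by blocked Gibbs sampling.

    ``testing_set`` may list record indices (masking whole multi-trait rows)
    or ``(record, trait)`` cells; masked cells never inform the fit beyond
    data augmentation and their posterior predictive means are reported in
    ``yHat``.
    """
    sampler = BMEGibbs(Y, Z1, X=X, block_size=settings.block_size, priors=priors,
                       testing_set=testing_set, fix_sigma_t=fix_sigma_t, fix_re=fix_re)
    if rng is None:
        rng = np.random.default_rng(settings.seed)
    acc = _Accumulator()
    for it in range(1, settings.n_iter + 1):
        sampler.step(rng)
        if it > settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
            acc.add(yHat=sampler.pred, beta=sampler.beta, b1=sampler.b1,
                    varTrait=sampler.Sigma_t, vare=sampler.Re, Se=sampler._Se_update)
    na = [tuple(ij) for ij in np.argwhere(sampler.mask)]
    return BMEFit(
        Y=sampler.Y_input, yHat=acc.mean("yHat"), SD_yHat=acc.sd("yHat"),
        beta=acc.mean("beta"), SD_beta=acc.sd("beta"),
        b1=acc.mean("b1"), SD_b1=acc.sd("b1"),
        varTrait=acc.mean("varTrait"), SD_varTrait=acc.sd("varTrait"),
        vare=acc.mean("vare"), SD_vare=acc.sd("vare"),
        dfe=sampler.nu_r + sampler.n, Se=acc.mean("Se"),
        NAvalues=na, n_iter=settings.n_iter, burn_in=settings.burn_in,
        thin=settings.thin,
    )
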