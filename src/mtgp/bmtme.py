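"""Bayesian multi-trait multi-environment model.

Fits ``Y = X beta + Z1 b1 + Z2 b2 + E`` where, in the whitened
parameterization produced by :func:`mtgp.data.build_design`,

* ``b1 ~ MN(0, I_J, Sigma_t)`` — line-by-trait effects,
* ``b2 ~ MN(0, Sigma_E (x) I_J, Sigma_t)`` — line-by-environment-by-trait
  effects; ``Sigma_E`` is the unstructured genetic (co)variance between
  environments,
* ``E ~ MN(0, I_n, Re)``.

The Gibbs cycle samples beta and the effect matrices from matrix-normal full
conditionals (effects in row blocks), and the three covariance matrices from
inverse-Wishart full conditionals.  The Sigma_E update treats the I x (J*L)
rearrangement of b2 as matrix-normal with row covariance Sigma_E, giving
scale increments ``M[i,k] = tr(B_i Sigma_t^-1 B_k')`` over the per-environment
slices B_i of b2 and df increment J*L.

Note the joint scale of (Sigma_E, Sigma_t) in the b2 prior is only identified
through their Kronecker product; correlations are identified, absolute scales
of the two factors are not constrained here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from ._masking import augment_masked, testing_mask
from .bme import BMEFit, MatrixPriors, _Accumulator
from .errors import DataValidationError
from .linalg import safe_cholesky
from .samplers import (ChainSettings, plan_blocks, sample_effect_block,
                       sample_inverse_wishart)

__all__ = ["BMTMEFit", "BMTMEGibbs", "fit_bmtme"]


@dataclass
class BMTMEFit(BMEFit):
    """BME summaries plus the interaction effects and environment covariance."""

    b2: np.ndarray = None
    SD_b2: np.ndarray = None
    varEnv: np.ndarray = None
    SD_varEnv: np.ndarray = None


class BMTMEGibbs:
    """One-sweep Gibbs kernel for the multi-trait multi-environment model."""

    def __init__(self, Y: np.ndarray, X: np.ndarray, Z1: np.ndarray, Z2: np.ndarray,
                 *, block_size: int = 50, priors: Optional[MatrixPriors] = None,
                 testing_set=None, fix_sigma_t: Optional[np.ndarray] = None,
                 fix_sigma_e: Optional[np.ndarray] = None,
                 fix_re: Optional[np.ndarray] = None,
                 n_env: Optional[int] = None):
        Y = np.asarray(Y, dtype=float)
        if Y.ndim != 2 or Y.shape[1] < 2:
            raise DataValidationError("Y must be n x L with L >= 2 traits")
        n, L = Y.shape
        X = np.asarray(X, dtype=float)
        Z1 = np.asarray(Z1, dtype=float)
        Z2 = np.asarray(Z2, dtype=float)
        I = n_env if n_env is not None else X.shape[1]
        if I < 2:
            raise DataValidationError(
                "the multi-environment model requires I >= 2 environments; "
                "use fit_bme for a single environment"
            )
        J = Z1.shape[1]
        if X.shape[0] != n or Z1.shape[0] != n or Z2.shape[0] != n:
            raise DataValidationError("X, Z1, Z2 must have one row per record of Y")
        if Z2.shape[1] != I * J:
            raise DataValidationError(
                f"Z2 has {Z2.shape[1]} columns; expected I*J = {I * J} "
                "(environment-major ordering from one DesignBundle)"
            )
        self.n, self.L, self.J, self.I = n, L, J, I
        self.X, self.Z1, self.Z2 = X, Z1, Z2

        nu_t, S_t, nu_r, S_r, nu_e, S_e = (priors or MatrixPriors()).resolve(L, I)
        self.nu_t, self.S_t, self.nu_r, self.S_r = nu_t, S_t, nu_r, S_r
        self.nu_env, self.S_env = nu_e, S_e
        self.fix_sigma_t = None if fix_sigma_t is None else np.asarray(fix_sigma_t, float)
        self.fix_sigma_e = None if fix_sigma_e is None else np.asarray(fix_sigma_e, float)
        self.fix_re = None if fix_re is None else np.asarray(fix_re, float)

        self.mask = testing_mask(testing_set, n, L) | np.isnan(Y)
        if self.mask.all(axis=0).any():
            raise DataValidationError("a trait has no observed (training) cells")
        self.Y_input = Y.copy()
        self.Y = Y.copy()
        for l in range(L):
            obs = ~self.mask[:, l]
            self.Y[~obs, l] = Y[obs, l].mean()

        if X.shape[1] > 0:
            self.XtX_inv = np.linalg.inv(X.T @ X)
            self.Lxx = safe_cholesky(self.XtX_inv)
        self.z1_plans = plan_blocks(Z1, block_size)
        # interaction blocks never straddle environments so the conditional
        # prior of a block stays isotropic: (Sigma_E^-1 (x) I)_BB = s * I
        groups = [np.arange(i * J, (i + 1) * J) for i in range(I)]
        self.z2_plans = plan_blocks(Z2, block_size, groups=groups)
        self.z2_env = [int(p.idx[0] // J) for p in self.z2_plans]

        self.beta = (self.XtX_inv @ (X.T @ self.Y)) if X.shape[1] > 0 else \
            np.zeros((0, L))
        self.b1 = np.zeros((J, L))
        self.b2 = np.zeros((I * J, L))
        obs_var = np.array([max(np.var(self.Y[:, l]), 1e-8) for l in range(L)])
        self.Sigma_t = (self.fix_sigma_t if self.fix_sigma_t is not None
                        else np.diag(obs_var / 3.0))
        self.Sigma_e = self.fix_sigma_e if self.fix_sigma_e is not None else np.eye(I)
        self.Re = self.fix_re if self.fix_re is not None else np.diag(obs_var / 3.0)
        self.F1 = Z1 @ self.b1
        self.F2 = Z2 @ self.b2
        self.pred = self.Y.copy()

    # -- simulator hooks ---------------------------------------------------
    def location(self) -> np.ndarray:
        XB = self.X @ self.beta if self.X.shape[1] else 0.0
        return XB + self.F1 + self.F2

    def set_response(self, Y: np.ndarray) -> None:
        self.Y = np.asarray(Y, dtype=float).copy()
        self.mask = np.zeros((self.n, self.L), dtype=bool)

    def simulate_response(self, rng: np.random.Generator) -> np.ndarray:
        E = rng.standard_normal((self.n, self.L)) @ safe_cholesky(self.Re).T
        Y = self.location() + E
        self.set_response(Y)
        return Y

    def _env_slices(self) -> List[np.ndarray]:
        return [self.b2[i * self.J:(i + 1) * self.J] for i in range(self.I)]

    # -- one sweep -----------------------------------------------------------
    def step(self, rng: np.random.Generator) -> None:
        Re_inv = np.linalg.inv(self.Re)
        St_inv = np.linalg.inv(self.Sigma_t)
        Se_inv = np.linalg.inv(self.Sigma_e)

        # (1) environment-by-trait fixed effects, flat prior
        if self.X.shape[1] > 0:
            E = self.Y - self.F1 - self.F2
            Bhat = self.XtX_inv @ (self.X.T @ E)
            Lre = safe_cholesky(self.Re)
            self.beta = Bhat + self.Lxx @ rng.standard_normal(self.beta.shape) @ Lre.T
        XB = self.X @ self.beta if self.X.shape[1] else np.zeros((self.n, self.L))

        # (2) line effects b1
        R1 = self.Y - XB - self.F2
        for plan in self.z1_plans:
            resid = R1 - self.F1 + plan.Z @ self.b1[plan.idx]
            new = sample_effect_block(plan, resid, St_inv, Re_inv, 1.0, None, rng)
            self.F1 += plan.Z @ (new - self.b1[plan.idx])
            self.b1[plan.idx] = new

        # (3) interaction effects b2, blocks within environments; the prior
        # of a block conditional on the other environments' rows has
        # precision Se_inv[i,i] * I and mean -(1/s) sum_{i'!=i} Se_inv[i,i'] b2[i',.]
        R2 = self.Y - XB - self.F1
        for plan, env_i in zip(self.z2_plans, self.z2_env):
            lines = plan.idx - env_i * self.J
            s = Se_inv[env_i, env_i]
            pm = np.zeros((len(plan.idx), self.L))
            for i2 in range(self.I):
                if i2 != env_i:
                    pm -= (Se_inv[env_i, i2] / s) * self.b2[i2 * self.J + lines]
            resid = R2 - self.F2 + plan.Z @ self.b2[plan.idx]
            new = sample_effect_block(plan, resid, St_inv, Re_inv, s, pm, rng)
            self.F2 += plan.Z @ (new - self.b2[plan.idx])
            self.b2[plan.idx] = new

        # (4) trait genetic covariance, pooling b1 and b2
        if self.fix_sigma_t is None:
            B = self._env_slices()
            S = self.S_t + self.b1.T @ self.b1
            for i in range(self.I):
                for i2 in range(self.I):
                    S += Se_inv[i, i2] * (B[i].T @ B[i2])
            S = 0.5 * (S + S.T)
            self.Sigma_t = sample_inverse_wishart(
                self.nu_t + self.J + self.I * self.J, S, rng)
            St_inv = np.linalg.inv(self.Sigma_t)

        # (5) environment genetic covariance from the matrix-normal likelihood
        # of the I x (J*L) rearrangement of b2
        if self.fix_sigma_e is None:
            B = self._env_slices()
            M = np.empty((self.I, self.I))
            BSt = [Bi @ St_inv for Bi in B]
            for i in range(self.I):
                for i2 in range(i, self.I):
                    M[i, i2] = M[i2, i] = float(np.sum(BSt[i] * B[i2]))
            self.Sigma_e = sample_inverse_wishart(
                self.nu_env + self.J * self.L, self.S_env + M, rng)

        # (6) residual covariance
        E = self.Y - XB - self.F1 - self.F2
        self._Se_update = self.S_r + E.T @ E
        if self.fix_re is None:
            self.Re = sample_inverse_wishart(self.nu_r + self.n, self._Se_update, rng)

        # (7) masked-cell augmentation
        mu = XB + self.F1 + self.F2
        self.pred = augment_masked(mu, self.Y, self.mask, self.Re, rng)


def fit_bmtme(Y: np.ndarray, X: np.ndarray, Z1: np.ndarray, Z2: np.ndarray,
              settings: ChainSettings, testing_set=None, *,
              priors: Optional[MatrixPriors] = None,
              fix_sigma_t: Optional[np.ndarray] = None,
              fix_sigma_e: Optional[np.ndarray] = None,
              fix_re: Optional[np.ndarray] = None,
              rng: Optional[np.random.Generator] = None) -> BMTMEFit:
    """Fit the multi-trait multi-environment model by blocked Gibbs sampling.

    X, Z1 and Z2 must come from the same :class:`~mtgp.data.DesignBundle`
    (consistent line/environment ordering, Z2 environment-major).
    """
    sampler = BMTMEGibbs(Y, X, Z1, Z2, block_size=settings.block_size,
                         priors=priors, testing_set=testing_set,
                         fix_sigma_t=fix_sigma_t, fix_sigma_e=fix_sigma_e,
                         fix_re=fix_re)
    if rng is None:
        rng = np.random.default_rng(settings.seed)
    acc = _Accumulator()
    for it in range(1, settings.n_iter + 1):
        sampler.step(rng)
        if it > settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
            acc.add(yHat=sampler.pred, beta=sampler.beta, b1=sampler.b1,
                    b2=sampler.b2, varTrait=sampler.Sigma_t, varEnv=sampler.Sigma_e,
                    vare=sampler.Re, Se=sampler._Se_update)
    na = [tuple(ij) for ij in np.argwhere(sampler.mask)]
    return BMTMEFit(
        Y=sampler.Y_input, yHat=acc.mean("yHat"), SD_yHat=acc.sd("yHat"),
        beta=acc.mean("beta"), SD_beta=acc.sd("beta"),
        b1=acc.mean("b1"), SD_b1=acc.sd("b1"),
        varTrait=acc.mean("varTrait"), SD_varTrait=acc.sd("varTrait"),
        vare=acc.mean("vare"), SD_vare=acc.sd("vare"),
        dfe=sampler.nu_r + sampler.n, Se=acc.mean("Se"), NAvalues=na,
        n_iter=settings.n_iter, burn_in=settings.burn_in, thin=settings.thin,
        b2=acc.mean("b2"), SD_b2=acc.sd("b2"),
        varEnv=acc.mean("varEnv"), SD_varEnv=acc.sd("varEnv"),
    )
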