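"""Synthetic marker, GRM and phenotype generators.

Data are drawn from the same generative model the samplers fit:
``Y = X beta + Z1 b1 + Z2 b2 + E`` with ``b1 ~ MN(0, I_J, Sigma_t)``,
``b2 ~ MN(0, Sigma_E (x) I_J, Sigma_t)`` (whitened scale; the genomic
relationship enters through Z1, Z2) and ``E ~ MN(0, I_n, Re)``.  Realized
effect matrices are stored on the truth object so tests can make exact
oracle comparisons.

Two presets emulate the structure of the toy datasets used throughout the
documentation: ``mada_like`` (30 wheat-style lines, 6 traits, one
environment) and ``maize_like`` (30 maize-style lines, 3 traits, 3
environments).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data import PhenotypeTable, canonicalize
from .errors import DataValidationError
from .linalg import GenomicRelationship, MarkerMatrix, safe_cholesky

__all__ = ["SimulationTruth", "simulate_markers", "simulate_bmtme",
           "grm_centered", "mada_like", "maize_like", "PRESETS"]


@dataclass
class SimulationTruth:
    """Known generative parameters plus (after simulation) realized effects.

    ``b1_true``/``b2_true`` are on the whitened scale (prior row covariance
    identity resp. ``Sigma_E (x) I``), matching the parameterization the
    fitters estimate.
    """

    beta_true: np.ndarray                 # I x L
    sigma_t_true: np.ndarray              # L x L
    re_true: np.ndarray                   # L x L
    sigma_e_true: Optional[np.ndarray] = None   # I x I, None for I == 1
    seed: int = 0
    b1_true: Optional[np.ndarray] = field(default=None)
    b2_true: Optional[np.ndarray] = field(default=None)

    def __post_init__(self):
        self.beta_true = np.atleast_2d(np.asarray(self.beta_true, dtype=float))
        for name in ("sigma_t_true", "re_true", "sigma_e_true"):
            m = getattr(self, name)
            if m is None:
                continue
            m = np.asarray(m, dtype=float)
            setattr(self, name, m)
            if np.abs(m - m.T).max() > 1e-10 * max(1.0, np.abs(m).max()):
                raise DataValidationError(f"{name} must be symmetric")
            if np.linalg.eigvalsh(m)[0] <= 0:
                raise DataValidationError(f"{name} must be positive definite")


def simulate_markers(J: int, p: int, maf_range=(0.05, 0.5), missing_rate: float = 0.0,
                     seed: int = 0, n_families: Optional[int] = None,
                     fst: float = 0.25) -> MarkerMatrix:
    """Binomial(2, f) dosage matrix with per-marker f uniform in ``maf_range``.

    With ``n_families`` set, lines are grouped into families whose allele
    frequencies are Balding-Nichols draws around the base frequency
    (divergence ``fst``), emulating the relatedness structure of a breeding
    panel; without it, lines are unrelated.
    """
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise DataValidationError("maf_range must satisfy 0 < lo <= hi <= 0.5")
    if not (0.0 <= missing_rate < 1.0):
        raise DataValidationError("missing_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(lo, hi, size=p)
    if n_families is not None and n_families > 0:
        if not 0.0 < fst < 1.0:
            raise DataValidationError("fst must lie in (0, 1)")
        c = (1.0 - fst) / fst
        fam_freqs = rng.beta(np.maximum(freqs * c, 1e-6),
                             np.maximum((1.0 - freqs) * c, 1e-6),
                             size=(n_families, p))
        fam = np.repeat(np.arange(n_families),
                        int(np.ceil(J / n_families)))[:J]
        vals = rng.binomial(2, fam_freqs[fam]).astype(float)
    else:
        vals = rng.binomial(2, freqs, size=(J, p)).astype(float)
    if missing_rate > 0:
        vals[rng.random((J, p)) < missing_rate] = np.nan
    return MarkerMatrix(vals, [f"L{j + 1:03d}" for j in range(J)],
                        [f"M{k + 1}" for k in range(p)])


def grm_centered(W: MarkerMatrix) -> GenomicRelationship:
    """Centered, frequency-scaled GRM: ``(W - 2f)(W - 2f)' / sum 2 f (1 - f)``.

    This is the caller-side centering conventionally applied before the raw
    cross-product GRM; it gives a near-unit average diagonal so simulated
    genetic variances are on the scale of ``Sigma_t``.
    """
    vals = W.values
    if np.isnan(vals).any():
        raise DataValidationError("impute or filter missing markers before building a GRM")
    f = vals.mean(axis=0) / 2.0
    denom = float((2.0 * f * (1.0 - f)).sum())
    if denom <= 0:
        raise DataValidationError("all markers are monomorphic; GRM undefined")
    Wc = vals - 2.0 * f
    return GenomicRelationship(Wc @ Wc.T / denom, list(W.line_ids))


def simulate_bmtme(G: GenomicRelationship, env_names: Sequence, trait_names: Sequence,
                   truth: SimulationTruth, gid_col: str = "GID",
                   env_col: str = "Env") -> PhenotypeTable:
    """Simulate a complete J x I phenotype layout from the generative model.

    Realized (whitened) effect matrices are written back onto ``truth``.
    With a single environment the interaction term is absent and the table
    has no environment column.
    """
    J = G.n_lines
    I, L = len(env_names), len(trait_names)
    if truth.beta_true.shape != (I, L):
        raise DataValidationError(
            f"beta_true has shape {truth.beta_true.shape}; expected ({I}, {L})")
    if truth.sigma_t_true.shape != (L, L) or truth.re_true.shape != (L, L):
        raise DataValidationError("trait covariance dimensions do not match traits")
    if I > 1 and (truth.sigma_e_true is None or truth.sigma_e_true.shape != (I, I)):
        raise DataValidationError("sigma_e_true must be I x I when I > 1")

    rng = np.random.default_rng(truth.seed)
    LG = safe_cholesky(G.values)
    Lt = safe_cholesky(truth.sigma_t_true)
    Lr = safe_cholesky(truth.re_true)

    b1 = rng.standard_normal((J, L)) @ Lt.T
    truth.b1_true = b1
    g1 = LG @ b1                                   # Z1 b1 on one environment block

    blocks = []
    if I > 1:
        LE = safe_cholesky(truth.sigma_e_true)
        z = rng.standard_normal((I, J, L))
        b2 = np.einsum("ik,kjl->ijl", LE, z) @ Lt.T   # MN(0, Sigma_E (x) I_J, Sigma_t)
        truth.b2_true = b2.reshape(I * J, L)
    for i in range(I):
        mu = truth.beta_true[i][None, :] + g1
        if I > 1:
            mu = mu + LG @ b2[i]
        E = rng.standard_normal((J, L)) @ Lr.T
        blocks.append(mu + E)

    frames = []
    for i, env in enumerate(env_names):
        df = pd.DataFrame(blocks[i], columns=list(trait_names))
        df.insert(0, gid_col, list(G.line_ids))
        if I > 1:
            df.insert(1, env_col, env)
        frames.append(df)
    data = pd.concat(frames, ignore_index=True)
    table = PhenotypeTable(data, gid_col=gid_col,
                           env_col=env_col if I > 1 else None,
                           trait_cols=list(trait_names))
    return canonicalize(table)


def _exchangeable(dim: int, rho: float, var: float = 1.0) -> np.ndarray:
    return var * ((1.0 - rho) * np.eye(dim) + rho * np.ones((dim, dim)))


def mada_like(seed: int = 0):
    """30 lines x 6 traits x 1 environment, wheat-style schema (GID + traits).

    Unit genetic and residual trait variances with exchangeable genetic
    correlation 0.3 and residual correlation 0.1; trait means differ so the
    table looks like field data.  Returns (markers, GRM, phenotypes, truth).
    """
    markers = simulate_markers(30, 500, (0.05, 0.5), 0.0, seed=seed, n_families=6)
    G = grm_centered(markers)
    traits = ["PH", "FL", "FE", "NS", "SY", "NP"]
    truth = SimulationTruth(
        beta_true=np.array([[10.0, 5.0, 8.0, 3.0, 20.0, 15.0]]),
        sigma_t_true=_exchangeable(6, 0.3),
        re_true=_exchangeable(6, 0.1),
        seed=seed + 1,
    )
    gids = [str(j + 1) for j in range(30)]
    Gnamed = GenomicRelationship(G.values, gids)
    pheno = simulate_bmtme(Gnamed, ["Env1"], traits, truth, gid_col="GID")
    markers.line_ids = gids
    return markers, Gnamed, pheno, truth


def maize_like(seed: int = 0):
    """30 lines x 3 traits x 3 environments, maize-style schema (Line, Env, traits).

    Unit-variance genetic trait covariance with correlation 0.5, environment
    covariance with correlation 0.6, residual correlation 0.2; environment-
    specific trait means.  Returns (markers, GRM, phenotypes, truth).
    """
    markers = simulate_markers(30, 500, (0.05, 0.5), 0.0, seed=seed, n_families=6)
    G = grm_centered(markers)
    traits = ["Yield", "ASI", "PH"]
    envs = ["EBU", "KAK", "KTI"]
    truth = SimulationTruth(
        beta_true=np.array([[6.0, 2.0, 235.0],
                            [6.5, 2.2, 240.0],
                            [7.0, 2.4, 245.0]]),
        sigma_t_true=_exchangeable(3, 0.5),
        sigma_e_true=_exchangeable(3, 0.6),
        re_true=_exchangeable(3, 0.2),
        seed=seed + 1,
    )
    gids = [f"CKDHL{j + 1:04d}" for j in range(30)]
    Gnamed = GenomicRelationship(G.values, gids)
    pheno = simulate_bmtme(Gnamed, envs, traits, truth, gid_col="Line", env_col="Env")
    markers.line_ids = gids
    return markers, Gnamed, pheno, truth


PRESETS = {"mada_like": mada_like, "maize_like": maize_like}
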