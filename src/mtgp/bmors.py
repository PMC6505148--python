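"""Bayesian multi-output regressor stacking (BMORS).

Two-stage prediction for multi-trait data built entirely from univariate
fits, so it is far cheaper than the full multi-trait multi-environment
sampler:

1. for each trait, a univariate Bayesian regression (the caller's component
   list: environment, genomic and interaction terms) produces predictions
   for every record, with testing cells masked;
2. the L stage-1 prediction vectors are standardized (per trait: subtract
   the mean, divide by the SD) and used as the only covariates — plus an
   intercept — of a second univariate meta-model per trait, which corrects
   each trait's predictions using the predictions of all traits.

:func:`fit_bmors` evaluates the scheme over a set of cross-validation
partitions; :func:`fit_bmors_env` holds out whole environments and trains on
the remaining ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .crossval import CVPartitionSet
from .data import PhenotypeTable, canonicalize
from .errors import DataValidationError
from .evaluate import metric_records
from .metrics import COMPLETE_COLUMNS, summarize
from .samplers import (KNOWN_MODELS, ChainSettings, PredictorComponent,
                       fit_univariate)

__all__ = ["StackedPredictors", "BMORSResult", "scale_predictions",
           "fit_bmors", "fit_bmors_env"]


@dataclass
class StackedPredictors:
    """Column-standardized stage-1 predictions plus the scale parameters."""

    zhat: np.ndarray
    means: np.ndarray
    sds: np.ndarray


@dataclass
class BMORSResult:
    records: pd.DataFrame
    summary: pd.DataFrame
    stage2_coefficients: List[np.ndarray] = field(default_factory=list)
    predictions: List[np.ndarray] = field(default_factory=list)


def scale_predictions(yhat: np.ndarray,
                      trait_names: Optional[Sequence[str]] = None) -> StackedPredictors:
    """Standardize each trait's stage-1 prediction vector (sample SD, n-1)."""
    yhat = np.atleast_2d(np.asarray(yhat, dtype=float))
    if yhat.ndim != 2:
        raise DataValidationError("stage-1 predictions must form an n x L matrix")
    means = yhat.mean(axis=0)
    sds = yhat.std(axis=0, ddof=1)
    bad = np.flatnonzero(sds == 0.0)
    if bad.size:
        name = trait_names[bad[0]] if trait_names else f"column {int(bad[0])}"
        raise DataValidationError(
            f"stage-1 predictions for trait {name} are constant (zero SD); cannot scale"
        )
    return StackedPredictors(zhat=(yhat - means) / sds, means=means, sds=sds)


def _check_cov_model(cov_model: str) -> None:
    if cov_model not in KNOWN_MODELS:
        raise DataValidationError(
            f"unknown covModel {cov_model!r}; known: {KNOWN_MODELS}")


def _two_stage_partition(Y: np.ndarray, test_idx: np.ndarray,
                         components: Sequence[PredictorComponent],
                         settings: ChainSettings, cov_model: str,
                         seedseq: np.random.SeedSequence,
                         stage1_folds: int = 5) -> Tuple[np.ndarray, np.ndarray]:
    """Run both stages for one partition; returns (stage2 yhat, stage2 coefs).

    Stage-1 predictions at testing cells come from a fit on all training
    records; stage-1 predictions at training cells are out-of-fold (an inner
    ``stage1_folds``-fold split of the training records), the stacked-
    generalization convention.  In-sample training predictions leak the
    training residual into the meta-model, which then down-weights (even
    sign-flips) the correlated traits' predictions; out-of-fold covariates
    keep the stage-2 coefficients honest.  ``stage1_folds=0`` restores plain
    in-sample stage-1 predictions.
    """
    n, L = Y.shape
    test_idx = np.asarray(test_idx, dtype=int)
    seeds = seedseq.spawn(2 * L + 1)
    assign_rng = np.random.default_rng(seeds[0])
    train = np.setdiff1d(np.arange(n), test_idx)
    k = min(stage1_folds, len(train)) if stage1_folds else 0
    folds = np.array_split(assign_rng.permutation(train), k) if k >= 2 else []
    stage1 = np.empty((n, L))
    for l in range(L):
        sub = seeds[1 + l].spawn(len(folds) + 1)
        y = Y[:, l].copy()
        y[test_idx] = np.nan
        fit = fit_univariate(y, components, settings,
                             rng=np.random.default_rng(sub[0]))
        stage1[:, l] = fit.yhat
        for fi, fold in enumerate(folds):
            y2 = y.copy()
            y2[fold] = np.nan
            f = fit_univariate(y2, components, settings,
                               rng=np.random.default_rng(sub[1 + fi]))
            stage1[fold, l] = f.yhat[fold]
    stacked = scale_predictions(stage1)
    yhat2 = np.empty((n, L))
    coefs = np.empty((L, L))
    meta = [PredictorComponent(stacked.zhat, cov_model, name="stacked")]
    for l in range(L):
        y = Y[:, l].copy()
        y[test_idx] = np.nan
        fit = fit_univariate(y, meta, settings,
                             rng=np.random.default_rng(seeds[1 + L + l]))
        yhat2[:, l] = fit.yhat
        coefs[l] = fit.effects[0]
    return yhat2, coefs


def fit_bmors(Y: np.ndarray, components: Sequence[PredictorComponent],
              settings: ChainSettings, partitions: CVPartitionSet,
              cov_model: str = "BRR", trait_names: Optional[Sequence[str]] = None,
              env_labels: Optional[np.ndarray] = None,
              stage1_folds: int = 5) -> BMORSResult:
    """Evaluate two-stage stacking over cross-validation partitions.

    Stage 1 is refit within every partition with the testing records masked,
    so no testing information leaks into the stage-2 covariates; training-cell
    covariates are additionally out-of-fold (see ``stage1_folds``).
    ``cov_model`` selects the prior of the stage-2 meta-model only; stage 1
    honors each component's own ``model_label``.
    """
    _check_cov_model(cov_model)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n, L = Y.shape
    if trait_names is None:
        trait_names = [f"T{l + 1}" for l in range(L)]
    for p in partitions.partitions:
        if p.size and (p.min() < 0 or p.max() >= n):
            raise DataValidationError("partition indices out of range for Y")
    rows = []
    result = BMORSResult(records=pd.DataFrame(), summary=pd.DataFrame())
    seeds = np.random.SeedSequence(settings.seed).spawn(partitions.n_partitions)
    for p, test_idx in enumerate(partitions.partitions, start=1):
        yhat2, coefs = _two_stage_partition(Y, test_idx, components, settings,
                                            cov_model, seeds[p - 1],
                                            stage1_folds=stage1_folds)
        result.predictions.append(yhat2)
        result.stage2_coefficients.append(coefs)
        rows += metric_records(Y, yhat2, test_idx, p, trait_names, env_labels)
    result.records = pd.DataFrame(rows, columns=COMPLETE_COLUMNS)
    result.summary = summarize(result.records)
    return result


def fit_bmors_env(table: PhenotypeTable, testing_envs: Sequence,
                  components: Sequence[PredictorComponent],
                  cov_model: str = "BRR",
                  settings: Optional[ChainSettings] = None,
                  stage1_folds: int = 0) -> BMORSResult:
    """Predict whole environments from the remaining ones (single partition).

    All trait cells of records in ``testing_envs`` are masked; metrics are
    reported per (environment, trait) for the testing environments only, with
    NaN standard errors since only one testing set exists.

    Stage-1 covariates default to in-sample here (``stage1_folds=0``): under
    whole-environment masking an inner fold removes a line's only remaining
    records, leaving relatives-only covariates whose quality differs sharply
    from the testing environment's, which miscalibrates the meta-model.
    """
    _check_cov_model(cov_model)
    if settings is None:
        raise DataValidationError("ChainSettings are required")
    table = canonicalize(table)
    if table.env_col is None:
        raise DataValidationError("the table has no environment column")
    all_envs = set(table.env_names)
    testing_envs = list(testing_envs)
    if not testing_envs:
        raise DataValidationError("testing_envs must be non-empty")
    unknown = [e for e in testing_envs if e not in all_envs]
    if unknown:
        raise DataValidationError(f"unknown environment(s): {unknown}")
    if set(testing_envs) == all_envs:
        raise DataValidationError(
            "testing_envs must be a proper subset: at least one environment "
            "must remain for training"
        )
    env_labels = table.envs
    test_idx = np.flatnonzero(np.isin(env_labels, testing_envs))
    Y = table.response_matrix()
    yhat2, coefs = _two_stage_partition(Y, test_idx, components, settings,
                                        cov_model,
                                        np.random.SeedSequence(settings.seed),
                                        stage1_folds=stage1_folds)
    rows = metric_records(Y, yhat2, test_idx, 1, table.trait_names, env_labels)
    records = pd.DataFrame(rows, columns=COMPLETE_COLUMNS)
    return BMORSResult(records=records, summary=summarize(records),
                       stage2_coefficients=[coefs], predictions=[yhat2])
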