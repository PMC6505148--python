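"""Cross-validated prediction evaluation for the BME and BMTME fitters.

Loops a fitter over the partitions of a :class:`~mtgp.crossval.CVPartitionSet`,
masking each testing set, and collects Pearson / MAAPE per
(environment, trait, partition) plus the averaged summary table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .bme import MatrixPriors, fit_bme
from .bmtme import fit_bmtme
from .crossval import CVPartitionSet
from .metrics import COMPLETE_COLUMNS, maape, pearson, summarize
from .samplers import ChainSettings

__all__ = ["CVResult", "cross_validate_bme", "cross_validate_bmtme", "metric_records"]


@dataclass
class CVResult:
    records: pd.DataFrame   # Environment, Trait, Partition, Pearson, MAAPE
    summary: pd.DataFrame   # Environment, Trait, Pearson, SE_Pearson, MAAPE, SE_MAAPE


def metric_records(Y_true: np.ndarray, yhat: np.ndarray, test_idx: np.ndarray,
                   partition: int, trait_names: Sequence[str],
                   env_labels: Optional[np.ndarray]) -> list:
    """Per-(environment, trait) metric rows for one partition's testing cells."""
    rows = []
    envs = [""] if env_labels is None else sorted(pd.unique(np.asarray(env_labels)[test_idx]))
    for env in envs:
        if env_labels is None:
            idx = np.asarray(test_idx)
        else:
            sel = np.asarray(env_labels)[test_idx] == env
            idx = np.asarray(test_idx)[sel]
        for l, trait in enumerate(trait_names):
            obs = Y_true[idx, l]
            keep = ~np.isnan(obs)
            if keep.sum() == 0:
                continue
            rows.append({"Environment": env, "Trait": trait, "Partition": partition,
                         "Pearson": pearson(obs[keep], yhat[idx, l][keep]),
                         "MAAPE": maape(obs[keep], yhat[idx, l][keep])})
    return rows


def _spawned_rngs(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def cross_validate_bme(Y: np.ndarray, Z1: np.ndarray, settings: ChainSettings,
                       partitions: CVPartitionSet, trait_names: Sequence[str],
                       env_labels: Optional[np.ndarray] = None,
                       priors: Optional[MatrixPriors] = None) -> CVResult:
    Y = np.asarray(Y, dtype=float)
    rows = []
    rngs = _spawned_rngs(settings.seed, partitions.n_partitions)
    for p, test_idx in enumerate(partitions.partitions, start=1):
        fit = fit_bme(Y, Z1, settings, testing_set=test_idx, priors=priors,
                      rng=rngs[p - 1])
        rows += metric_records(Y, fit.yHat, test_idx, p, trait_names, env_labels)
    records = pd.DataFrame(rows, columns=COMPLETE_COLUMNS)
    return CVResult(records=records, summary=summarize(records))


def cross_validate_bmtme(Y: np.ndarray, X: np.ndarray, Z1: np.ndarray,
                         Z2: np.ndarray, settings: ChainSettings,
                         partitions: CVPartitionSet, trait_names: Sequence[str],
                         env_labels: np.ndarray,
                         priors: Optional[MatrixPriors] = None) -> CVResult:
    Y = np.asarray(Y, dtype=float)
    rows = []
    rngs = _spawned_rngs(settings.seed, partitions.n_partitions)
    for p, test_idx in enumerate(partitions.partitions, start=1):
        fit = fit_bmtme(Y, X, Z1, Z2, settings, testing_set=test_idx,
                        priors=priors, rng=rngs[p - 1])
        rows += metric_records(Y, fit.yHat, test_idx, p, trait_names, env_labels)
    records = pd.DataFrame(rows, columns=COMPLETE_COLUMNS)
    return CVResult(records=records, summary=summarize(records))
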