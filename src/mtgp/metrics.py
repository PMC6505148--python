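"""Prediction-accuracy metrics and the mean +/- SE summary table.

Pearson's correlation and the mean arctangent absolute percentage error
(MAAPE) are computed per (environment, trait, partition) on testing cells;
:func:`summarize` averages them across partitions and attaches standard
errors (NaN when only one testing set exists, since no spread can be
estimated).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["pearson", "maape", "summarize"]

#: column order of the per-partition ("complete") metrics table
COMPLETE_COLUMNS = ["Environment", "Trait", "Partition", "Pearson", "MAAPE"]
#: column order of the summary table
SUMMARY_COLUMNS = ["Environment", "Trait", "Pearson", "SE_Pearson", "MAAPE", "SE_MAAPE"]


def pearson(obs, pred) -> float:
    """Product-moment correlation; NaN when either vector has zero variance."""
    obs = np.asarray(obs, dtype=float).ravel()
    pred = np.asarray(pred, dtype=float).ravel()
    if obs.size != pred.size or obs.size < 2:
        return float("nan")
    so, sp = obs.std(), pred.std()
    if so == 0.0 or sp == 0.0:
        return float("nan")
    return float(np.corrcoef(obs, pred)[0, 1])


def maape(obs, pred) -> float:
    """Mean arctangent absolute percentage error, bounded in [0, pi/2].

    Each pair contributes ``arctan(|(obs - pred) / obs|)``; an exact match
    contributes 0 even at obs = 0, while obs = 0 with pred != obs contributes
    arctan(inf) = pi/2.  Unlike MAPE this stays defined when the response
    contains zeros.
    """
    obs = np.asarray(obs, dtype=float).ravel()
    pred = np.asarray(pred, dtype=float).ravel()
    terms = np.empty(obs.size)
    exact = obs == pred
    zero = (obs == 0.0) & ~exact
    rest = ~exact & ~zero
    terms[exact] = 0.0
    terms[zero] = np.pi / 2.0
    terms[rest] = np.arctan(np.abs((obs[rest] - pred[rest]) / obs[rest]))
    return float(terms.mean())


def summarize(records: pd.DataFrame) -> pd.DataFrame:
    """Average per-partition metrics into the standard summary table.

    ``records`` needs columns Trait, Partition, Pearson, MAAPE and optionally
    Environment (absent or blank for single-environment fits).  The SE is the
    sample SD across partitions divided by sqrt(#partitions); with a single
    partition it is NaN.  Rows are ordered by environment then trait.
    """
    df = records.copy()
    if "Environment" not in df.columns:
        df["Environment"] = ""
    df["Environment"] = df["Environment"].fillna("")
    rows = []
    for (env, trait), grp in df.groupby(["Environment", "Trait"], sort=True):
        m = len(grp)
        se_p = grp["Pearson"].std(ddof=1) / np.sqrt(m) if m > 1 else float("nan")
        se_m = grp["MAAPE"].std(ddof=1) / np.sqrt(m) if m > 1 else float("nan")
        rows.append({
            "Environment": env, "Trait": trait,
            "Pearson": grp["Pearson"].mean(), "SE_Pearson": se_p,
            "MAAPE": grp["MAAPE"].mean(), "SE_MAAPE": se_m,
        })
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
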