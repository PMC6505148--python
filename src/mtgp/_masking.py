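"""Masked-cell bookkeeping and conditional-normal data augmentation.

Shared by the BME and BMTME Gibbs samplers: testing sets are converted to a
boolean n x L mask, and each sweep the masked cells are (a) summarized by
their conditional predictive mean given the observed traits of the same
record and (b) re-drawn from that conditional normal (data augmentation).
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .errors import DataValidationError
from .linalg import safe_cholesky


def testing_mask(testing_set, n: int, L: int) -> np.ndarray:
    """Normalize a testing set to a boolean n x L cell mask.

    Accepts ``None``, a collection of record indices (masking whole
    multi-trait rows), or a collection of ``(record, trait)`` cells.
    """
    mask = np.zeros((n, L), dtype=bool)
    if testing_set is None:
        return mask
    items = list(np.asarray(testing_set).tolist()) if not isinstance(testing_set, (list, tuple)) \
        else list(testing_set)
    for item in items:
        if np.isscalar(item) or isinstance(item, (int, np.integer)):
            r = int(item)
            if not 0 <= r < n:
                raise DataValidationError(f"testing record index {r} out of range [0, {n})")
            mask[r, :] = True
        else:
            r, t = (int(item[0]), int(item[1]))
            if not (0 <= r < n and 0 <= t < L):
                raise DataValidationError(f"testing cell ({r}, {t}) out of range")
            mask[r, t] = True
    return mask


def augment_masked(mu: np.ndarray, Y: np.ndarray, mask: np.ndarray,
                   Re: np.ndarray, rng: Optional[np.random.Generator]) -> np.ndarray:
    """Predictive means for masked cells; redraws them in-place when rng given.

    For a record with masked traits m and observed traits o, the conditional
    distribution under residual covariance Re is normal with mean
    ``mu_m + Re[m,o] Re[o,o]^-1 (y_o - mu_o)`` and covariance given by the
    Schur complement.  Returns the full n x L matrix whose observed cells are
    ``mu`` and masked cells the conditional means (the per-iteration
    predictive surface accumulated into yHat).
    """
    pred = mu.copy()
    if not mask.any():
        return pred
    patterns, inverse = np.unique(mask, axis=0, return_inverse=True)
    for pi, pat in enumerate(patterns):
        if not pat.any():
            continue
        rows = np.flatnonzero(inverse == pi)
        m = np.flatnonzero(pat)
        o = np.flatnonzero(~pat)
        if o.size == 0:
            cond_mean = mu[np.ix_(rows, m)]
            S = Re[np.ix_(m, m)]
        else:
            Roo = Re[np.ix_(o, o)]
            K = np.linalg.solve(Roo, Re[np.ix_(o, m)]).T          # m x o
            resid_o = Y[np.ix_(rows, o)] - mu[np.ix_(rows, o)]
            cond_mean = mu[np.ix_(rows, m)] + resid_o @ K.T
            S = Re[np.ix_(m, m)] - K @ Re[np.ix_(o, m)]
        pred[np.ix_(rows, m)] = cond_mean
        if rng is not None:
            Ls = safe_cholesky(0.5 * (S + S.T))
            z = rng.standard_normal((rows.size, m.size))
            Y[np.ix_(rows, m)] = cond_mean + z @ Ls.T
    return pred
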