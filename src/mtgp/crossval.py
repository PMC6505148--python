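"""Testing-set designs for prediction-accuracy evaluation.

Two schemes over the (line, environment) cells of a canonicalized phenotype
table:

* random cross-validation — per partition, ``round(p_testing * N)`` lines are
  drawn (with replacement iff fewer lines than draws exist), one available
  environment is picked per drawn line, and the selected distinct cells form
  the testing set;
* K-fold (CV2-style) — records are dealt into near-equal disjoint folds such
  that each line's records spread across distinct folds, so a line tested in
  some environments is trained in others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List

import numpy as np
import pandas as pd

from .data import PhenotypeTable, canonicalize
from .errors import DataValidationError

__all__ = ["CVPartitionSet", "cv_random_part", "cv_kfold"]


@dataclass
class CVPartitionSet:
    """Indexed testing sets; indices refer to rows of the canonical table."""

    partitions: List[np.ndarray]
    scheme: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.partitions = [np.asarray(p, dtype=int) for p in self.partitions]
        for p in self.partitions:
            if len(np.unique(p)) != len(p):
                raise DataValidationError("a partition contains duplicate record indices")

    @property
    def n_partitions(self) -> int:
        return len(self.partitions)

    def to_frame(self, table: PhenotypeTable = None) -> pd.DataFrame:
        rows = []
        for pi, part in enumerate(self.partitions, start=1):
            for r in part:
                row = {"partition": pi, "record_index": int(r)}
                if table is not None:
                    row["gid"] = table.gids[r]
                    if table.env_col:
                        row["env"] = table.envs[r]
                rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path, table: PhenotypeTable = None) -> None:
        self.to_frame(table).to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "CVPartitionSet":
        df = pd.read_csv(path)
        parts = [grp["record_index"].to_numpy(dtype=int)
                 for _, grp in df.groupby("partition", sort=True)]
        return cls(parts, scheme="file", params={"path": str(path)})


def cv_random_part(table: PhenotypeTable, n_partitions: int, p_testing: float,
                   seed: int = 0) -> CVPartitionSet:
    """Random cross-validation over (line, environment) cells.

    Per partition, ``m = round(p_testing * N)`` lines are drawn from the J
    available lines — with replacement iff ``J < m``, without otherwise — and
    for each drawn line one of its observed environments is picked uniformly.
    Duplicate cells collapse, so testing sets have at most m cells.
    """
    if not 0.0 < p_testing < 1.0:
        raise DataValidationError("p_testing must lie strictly between 0 and 1")
    if n_partitions < 1:
        raise DataValidationError("n_partitions must be >= 1")
    table = canonicalize(table)
    N = table.n_records
    m = int(np.floor(p_testing * N + 0.5))  # round half-up
    if m == 0:
        raise DataValidationError("p_testing * N rounds to zero testing cells")
    lines = table.line_names
    J = len(lines)
    gids = table.gids
    records_of_line = {g: np.flatnonzero(gids == g) for g in lines}
    rng = np.random.default_rng(seed)
    parts = []
    for _ in range(n_partitions):
        drawn = rng.choice(J, size=m, replace=J < m)
        cells = set()
        for j in drawn:
            recs = records_of_line[lines[j]]
            cells.add(int(recs[rng.integers(len(recs))]))
        parts.append(np.array(sorted(cells), dtype=int))
    return CVPartitionSet(parts, scheme="random",
                          params={"n_partitions": n_partitions,
                                  "p_testing": p_testing, "seed": seed})


def cv_kfold(table: PhenotypeTable, k: int, seed: int = 0) -> CVPartitionSet:
    """K-fold partitioning with per-line environment spreading (CV2).

    Each line's records are shuffled and dealt round-robin onto a shuffled
    fold order with a pointer shared across lines, so folds are disjoint and
    near-equal (sizes differ by at most one) and a line's records land in
    distinct folds whenever the line has at most k records.
    """
    table = canonicalize(table)
    N = table.n_records
    if not 2 <= k <= N:
        raise DataValidationError(f"k must satisfy 2 <= k <= {N}")
    rng = np.random.default_rng(seed)
    gids = table.gids
    lines = list(table.line_names)
    rng.shuffle(lines)
    fold_order = rng.permutation(k)
    folds: List[list] = [[] for _ in range(k)]
    t = 0
    for g in lines:
        recs = np.flatnonzero(gids == g)
        recs = rng.permutation(recs)
        for r in recs:
            folds[fold_order[t % k]].append(int(r))
            t += 1
    parts = [np.array(sorted(f), dtype=int) for f in folds]
    return CVPartitionSet(parts, scheme="kfold", params={"k": k, "seed": seed})
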