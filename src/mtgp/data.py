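"""Phenotype-table ingestion, canonical ordering, marker QC and design matrices.

The multi-trait multi-environment model operates on a long-format phenotype
table (one row per line-by-environment record, one column per trait).  Rows
must be ordered by environment then line before design matrices are built;
this module owns that canonical ordering and the construction of the
Cholesky-whitened designs

    X   environment incidence (one column per environment, no intercept)
    Z1  = ZG  @ chol(G)          line design, G the genomic relationship
    Z2  = ZEG @ chol(I_I (x) G)  line-by-environment interaction design

so that downstream samplers work with effects whose prior row covariance is
the identity (lines) or ``Sigma_E (x) I`` (line-by-environment).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DataValidationError
from .linalg import GenomicRelationship, MarkerMatrix, safe_cholesky

__all__ = [
    "PhenotypeTable",
    "DesignBundle",
    "read_phenotypes",
    "canonicalize",
    "filter_markers",
    "build_design",
]

#: tokens accepted as missing trait values in delimited files
MISSING_TOKENS = ("", "NA")


def _sort_key(values):
    """Numeric-aware sort keys: integer-like ids sort numerically, else as strings."""
    svals = [str(v) for v in values]
    try:
        return [int(s) for s in svals]
    except ValueError:
        return svals


@dataclass
class PhenotypeTable:
    """Long-format phenotype records: line id, optional environment, L traits."""

    data: pd.DataFrame
    gid_col: str = "GID"
    env_col: Optional[str] = None
    trait_cols: Sequence[str] = field(default_factory=list)

    def __post_init__(self):
        if self.gid_col not in self.data.columns:
            raise DataValidationError(f"column {self.gid_col!r} not in table")
        if self.env_col is not None and self.env_col not in self.data.columns:
            raise DataValidationError(f"column {self.env_col!r} not in table")
        if not list(self.trait_cols):
            reserved = {self.gid_col, self.env_col}
            self.trait_cols = [c for c in self.data.columns if c not in reserved]
        missing = [c for c in self.trait_cols if c not in self.data.columns]
        if missing:
            raise DataValidationError(f"trait columns absent: {missing}")
        if len(self.data) == 0:
            raise DataValidationError("phenotype table has no records")
        key_cols = [self.gid_col] + ([self.env_col] if self.env_col else [])
        dup = self.data.duplicated(subset=key_cols)
        if dup.any():
            row = self.data.loc[dup, key_cols].iloc[0].tolist()
            raise DataValidationError(f"duplicate (gid, env) record: {row}")
        for c in self.trait_cols:
            if not np.issubdtype(self.data[c].dtype, np.number):
                raise DataValidationError(f"trait column {c!r} is not numeric")

    # -- views ---------------------------------------------------------------
    @property
    def n_records(self) -> int:
        return len(self.data)

    @property
    def n_traits(self) -> int:
        return len(self.trait_cols)

    @property
    def trait_names(self) -> list:
        return list(self.trait_cols)

    @property
    def gids(self) -> np.ndarray:
        return self.data[self.gid_col].to_numpy()

    @property
    def envs(self) -> Optional[np.ndarray]:
        return self.data[self.env_col].to_numpy() if self.env_col else None

    @property
    def line_names(self) -> list:
        """Unique line identifiers in canonical (numeric-aware) order."""
        uniq = pd.unique(self.gids)
        order = np.argsort(_sort_key(uniq), kind="stable")
        return [uniq[i] for i in order]

    @property
    def env_names(self) -> list:
        if self.env_col is None:
            return ["Env1"]
        uniq = pd.unique(self.envs)
        order = np.argsort(_sort_key(uniq), kind="stable")
        return [uniq[i] for i in order]

    def response_matrix(self) -> np.ndarray:
        """n x L trait matrix (float, nan for missing cells)."""
        return self.data[list(self.trait_cols)].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        cols = [self.gid_col] + ([self.env_col] if self.env_col else []) + list(self.trait_cols)
        self.data[cols].to_csv(path, index=False)


def read_phenotypes(path, gid_col: str = "GID", env_col: Optional[str] = None,
                    trait_cols: Optional[Sequence[str]] = None) -> PhenotypeTable:
    """Read a delimited phenotype file.

    Empty cells and ``NA`` are treated as missing trait values; any other
    non-numeric trait cell raises an error naming the offending data row.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if len(raw) == 0:
        raise DataValidationError(f"{path}: no data rows")
    for col in (gid_col, env_col):
        if col is not None and col not in raw.columns:
            raise DataValidationError(f"{path}: column {col!r} not found")
    if trait_cols is None:
        reserved = {gid_col, env_col}
        trait_cols = [c for c in raw.columns if c not in reserved]
    df = raw[[gid_col] + ([env_col] if env_col else [])].copy()
    for c in trait_cols:
        if c not in raw.columns:
            raise DataValidationError(f"{path}: trait column {c!r} not found")
        cell = raw[c].str.strip()
        parsed = pd.to_numeric(cell, errors="coerce")
        bad = parsed.isna() & ~cell.isin(MISSING_TOKENS)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise DataValidationError(
                f"{path}: non-numeric value {cell.iloc[row]!r} in column {c!r}, data row {row + 1}"
            )
        df[c] = parsed.astype(float)
    return PhenotypeTable(df, gid_col=gid_col, env_col=env_col, trait_cols=list(trait_cols))


def canonicalize(table: PhenotypeTable) -> PhenotypeTable:
    """Sort records by (environment, line id), ascending; idempotent.

    Integer-like identifiers sort numerically, other identifiers sort
    lexicographically (plain byte order, not locale collation).
    """
    df = table.data
    keys = []
    if table.env_col:
        keys.append(np.asarray(_sort_key(df[table.env_col])))
    keys.append(np.asarray(_sort_key(df[table.gid_col])))
    order = np.lexsort(keys[::-1])
    out = df.iloc[order].reset_index(drop=True)
    return PhenotypeTable(out, gid_col=table.gid_col, env_col=table.env_col,
                          trait_cols=list(table.trait_cols))


def filter_markers(W: MarkerMatrix, max_missing: float = 0.20, min_maf: float = 0.05,
                   seed: int = 0) -> MarkerMatrix:
    """Marker QC: drop high-missingness markers, impute, drop low-MAF markers.

    1. markers with missing fraction > ``max_missing`` are removed;
    2. remaining missing entries are imputed by Binomial(2, f) draws from the
       marker's observed allele frequency f (seeded);
    3. markers with minor allele frequency < ``min_maf`` are removed, with the
       frequency computed after imputation.
    """
    vals = W.values
    ok = vals[~np.isnan(vals)]
    if ok.size and not np.isin(ok, (0.0, 1.0, 2.0)).all():
        raise DataValidationError("marker dosages must be coded 0/1/2 (or missing)")
    miss_frac = np.isnan(vals).mean(axis=0)
    keep1 = miss_frac <= max_missing
    vals = vals[:, keep1]
    names = [m for m, k in zip(W.marker_ids, keep1) if k]

    rng = np.random.default_rng(seed)
    vals = vals.copy()
    for k in range(vals.shape[1]):
        col = vals[:, k]
        nas = np.isnan(col)
        if nas.any():
            obs = col[~nas]
            freq = obs.mean() / 2.0 if obs.size else 0.0
            col[nas] = rng.binomial(2, freq, size=nas.sum()).astype(float)

    f = vals.mean(axis=0) / 2.0
    maf = np.minimum(f, 1.0 - f)
    keep2 = maf >= min_maf
    if not keep2.any():
        raise DataValidationError("all markers removed by QC (missingness/MAF filters)")
    return MarkerMatrix(vals[:, keep2], list(W.line_ids),
                        [m for m, k in zip(names, keep2) if k])


@dataclass
class DesignBundle:
    """Whitened design matrices of the multi-trait multi-environment model."""

    X: np.ndarray          # n x I environment incidence
    Z1: np.ndarray         # n x J whitened line design (ZG @ chol(G))
    Z2: Optional[np.ndarray]  # n x (I*J) whitened interaction design, None when I == 1
    Z_line: np.ndarray     # raw line incidence ZG
    Z_env_line: Optional[np.ndarray]  # raw interaction incidence ZEG
    line_order: list
    env_order: list
    trait_names: list

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def I(self) -> int:  # noqa: E743 - conventional symbol
        return self.X.shape[1]

    @property
    def J(self) -> int:
        return self.Z1.shape[1]

    @property
    def L(self) -> int:
        return len(self.trait_names)


def build_design(table: PhenotypeTable, G: GenomicRelationship) -> DesignBundle:
    """Build X, Z1, Z2 for a (canonicalized) phenotype table and GRM.

    The interaction design columns are environment-major: column
    ``i * J + j`` corresponds to environment ``env_order[i]`` and line
    ``line_order[j]``, matching the layout of ``I_I (x) G``.  With a single
    environment X is one all-ones column and Z2 is absent.
    """
    table = canonicalize(table)
    line_order = table.line_names
    env_order = table.env_names
    J, I, n = len(line_order), len(env_order), table.n_records

    Gsub = G.reindex(line_order)
    LG = safe_cholesky(Gsub.values)

    line_pos = {g: j for j, g in enumerate(line_order)}
    rows_line = np.array([line_pos[g] for g in table.gids])
    ZG = np.zeros((n, J))
    ZG[np.arange(n), rows_line] = 1.0
    Z1 = ZG @ LG

    if table.env_col is None or I == 1:
        X = np.ones((n, 1))
        return DesignBundle(X, Z1, None, ZG, None, line_order, env_order,
                            table.trait_names)

    env_pos = {e: i for i, e in enumerate(env_order)}
    rows_env = np.array([env_pos[e] for e in table.envs])
    X = np.zeros((n, I))
    X[np.arange(n), rows_env] = 1.0
    ZEG = np.zeros((n, I * J))
    ZEG[np.arange(n), rows_env * J + rows_line] = 1.0
    # chol(I_I (x) G) = I_I (x) chol(G): block-diagonal lower factor
    Z2 = ZEG @ np.kron(np.eye(I), LG)
    return DesignBundle(X, Z1, Z2, ZG, ZEG, line_order, env_order, table.trait_names)
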