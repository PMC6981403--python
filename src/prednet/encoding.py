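"""One-hot encoding of categorical survey tables with group bookkeeping.

Every k-level categorical variable becomes k binary indicator columns
(full one-hot, no reference level dropped), because every dummy later
serves as a prediction target in its own right.  The module also enforces
the anti-leakage rule: dummies derived from the same source variable are
never offered as predictors for each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING_LABEL = "MISSING"


@dataclass
class CategoricalTable:
    """A survey table: subjects x categorical variables, optional stratum.

    Parameters
    ----------
    data : pandas.DataFrame
        One row per subject, one column per categorical variable; all
        values are treated as string labels.  Missing cells (NaN or empty
        string) are mapped to the reserved ``MISSING`` label.
    stratum : pandas.Series, optional
        Per-subject stratum label (e.g. geographic region), aligned with
        ``data``.  Never listed among the analysis variables.
    """

    data: pd.DataFrame
    stratum: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.data.shape[1] < 1 or self.data.shape[0] < 1:
            raise ValueError("no data: table needs >=1 variable and >=1 subject")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate variable names: {dups}")
        clean = self.data.astype("object").copy()
        for col in clean.columns:
            vals = clean[col]
            mask = vals.isna() | (vals.astype(str).str.strip() == "")
            vals = vals.astype(str)
            vals[mask] = MISSING_LABEL
            clean[col] = vals
        self.data = clean
        if self.stratum is not None:
            self.stratum = self.stratum.astype(str)
            if len(self.stratum) != len(self.data):
                raise ValueError("stratum length does not match table")

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @classmethod
    def from_csv(
        cls,
        path,
        stratum: str | None = None,
        sep: str = ",",
        missing_sentinel: str = "",
    ) -> "CategoricalTable":
        """Read a delimited file; ``stratum`` names the stratum column."""
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
        df = df.replace(missing_sentinel, np.nan) if missing_sentinel else df
        strat = None
        if stratum is not None:
            if stratum not in df.columns:
                raise ValueError(f"stratum column {stratum!r} not in input")
            strat = df[stratum]
            df = df.drop(columns=[stratum])
        return cls(df, strat)


@dataclass
class EncodedMatrix:
    """Binary dummy matrix with a map from each dummy to its source variable.

    ``columns`` are named ``<variable>=<level>``; within each variable's
    group of columns every row carries exactly one 1.  ``degenerate`` lists
    columns that are constant (all 0 or all 1) in the data.
    """

    columns: list[str]
    data: np.ndarray  # subjects x dummies, uint8
    groups: dict[str, list[str]]
    degenerate: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self._col_index = {c: i for i, c in enumerate(self.columns)}
        self._group_of = {
            col: var for var, cols in self.groups.items() for col in cols
        }

    def column_index(self, name: str) -> int:
        try:
            return self._col_index[name]
        except KeyError:
            raise KeyError(f"unknown dummy column {name!r}") from None

    def group_of(self, name: str) -> str:
        self.column_index(name)
        return self._group_of[name]

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    def subset_rows(self, row_idx: np.ndarray) -> "EncodedMatrix":
        """Row-subset (e.g. one stratum) with degenerate set recomputed."""
        sub = self.data[row_idx]
        return EncodedMatrix(
            columns=list(self.columns),
            data=sub,
            groups={v: list(c) for v, c in self.groups.items()},
            degenerate=_constant_columns(self.columns, sub),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, columns=self.columns)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def write_groups_tsv(self, path) -> None:
        rows = [(col, var) for var, cols in self.groups.items() for col in cols]
        pd.DataFrame(rows, columns=["dummy", "variable"]).to_csv(
            path, sep="\t", index=False
        )


def _constant_columns(columns: list[str], data: np.ndarray) -> set[str]:
    if data.shape[0] == 0:
        return set(columns)
    mx = data.max(axis=0)
    mn = data.min(axis=0)
    return {c for c, lo, hi in zip(columns, mn, mx) if lo == hi}


def one_hot_encode(table: CategoricalTable) -> EncodedMatrix:
    """Expand every categorical variable into its full set of level dummies.

    Column order is deterministic: variables in table order, levels in
    lexicographic order within each variable.
    """
    if table.n_subjects < 2:
        raise ValueError("no data: need >=2 subjects to encode")
    columns: list[str] = []
    groups: dict[str, list[str]] = {}
    blocks: list[np.ndarray] = []
    for var in table.variables:
        vals = table.data[var].to_numpy()
        levels = sorted(set(vals))
        names = [f"{var}={lev}" for lev in levels]
        groups[var] = names
        columns.extend(names)
        block = (vals[:, None] == np.array(levels, dtype=object)[None, :])
        blocks.append(block.astype(np.uint8))
    data = np.concatenate(blocks, axis=1)
    return EncodedMatrix(
        columns=columns,
        data=data,
        groups=groups,
        degenerate=_constant_columns(columns, data),
    )


def predictor_mask(encoded: EncodedMatrix, target: str) -> list[str]:
    """All dummy columns usable as predictors for ``target``.

    Excludes every dummy sharing the target's source variable (the target
    itself included): sibling dummies determine the target trivially under
    full one-hot coding and would leak the answer into the model.
    """
    var = encoded.group_of(target)  # raises on unknown target
    excluded = set(encoded.groups[var])
    return [c for c in encoded.columns if c not in excluded]


def decode_group(encoded: EncodedMatrix, variable: str) -> np.ndarray:
    """Recover the original label column of ``variable`` from its dummies."""
    cols = encoded.groups[variable]
    idx = np.array([encoded.column_index(c) for c in cols])
    block = encoded.data[:, idx]
    levels = np.array([c.split("=", 1)[1] for c in cols], dtype=object)
    if not np.all(block.sum(axis=1) == 1):
        raise ValueError(f"group {variable!r} is not one-hot")
    return levels[block.argmax(axis=1)]


def read_encoded_tsv(matrix_path, groups_path) -> EncodedMatrix:
    """Round-trip counterpart of ``write_tsv`` / ``write_groups_tsv``."""
    df = pd.read_csv(matrix_path, sep="\t")
    gdf = pd.read_csv(groups_path, sep="\t")
    groups: dict[str, list[str]] = {}
    for dummy, var in zip(gdf["dummy"], gdf["variable"]):
        groups.setdefault(var, []).append(dummy)
    data = df.to_numpy(dtype=np.uint8)
    cols = list(df.columns)
    return EncodedMatrix(
        columns=cols,
        data=data,
        groups=groups,
        degenerate=_constant_columns(cols, data),
    )
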