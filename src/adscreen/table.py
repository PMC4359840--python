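"""Decision tables: the discrete data model shared by every stage of the pipeline.

A decision table is a finite set of subjects (rows) described by discrete
condition attributes (scale-item scores) plus one categorical decision
attribute (the diagnostic class, e.g. Normal / MCI / AD).  Values are
categorical tokens: the rough-set machinery only ever asks whether two
values are *equal*, so no numeric interpretation is imposed.  An optional
integer-normalisation flag collapses tokens such as ``"5"`` and ``"5.0"``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TableError",
    "DecisionTable",
    "load_decision_table",
    "write_decision_table",
    "project",
    "table_from_arrays",
]


class TableError(ValueError):
    """Raised when a decision table violates its structural contract."""


def _as_str_frame(data: pd.DataFrame) -> pd.DataFrame:
    out = data.copy()
    for col in out.columns:
        out[col] = out[col].astype(str)
    return out


@dataclass(frozen=True)
class DecisionTable:
    """Finite objects x discrete condition attributes + one decision attribute.

    The value mapping f(object, attribute) is total: empty cells are rejected
    at construction time.  Objects are identified by their row index (rows may
    be duplicated — subjects are anonymous).
    """

    data: pd.DataFrame
    decision_attribute: str
    _cache: dict = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self) -> None:
        cols = list(self.data.columns)
        if len(cols) != len(set(cols)):
            dupes = sorted({c for c in cols if cols.count(c) > 1})
            raise TableError(f"duplicate column names: {dupes}")
        if self.decision_attribute not in cols:
            raise TableError(
                f"decision column {self.decision_attribute!r} not present"
            )
        if len(cols) < 2:
            raise TableError("need at least one condition attribute")
        if len(self.data) < 1:
            raise TableError("table has no objects")
        object.__setattr__(self, "data", _as_str_frame(self.data.reset_index(drop=True)))
        for col in self.data.columns:
            empties = np.flatnonzero(self.data[col].str.strip() == "")
            if empties.size:
                raise TableError(
                    f"empty value at row {int(empties[0]) + 1}, column {col!r}"
                )

    # -- basic views -------------------------------------------------------

    @property
    def condition_attributes(self) -> tuple[str, ...]:
        return tuple(c for c in self.data.columns if c != self.decision_attribute)

    @property
    def n_objects(self) -> int:
        return len(self.data)

    @property
    def objects(self) -> range:
        return range(len(self.data))

    @property
    def class_labels(self) -> tuple[str, ...]:
        """Decision values in order of first appearance."""
        seen: dict[str, None] = {}
        for v in self.data[self.decision_attribute]:
            seen.setdefault(v, None)
        return tuple(seen)

    def value(self, obj: int, attribute: str) -> str:
        return self.data.at[obj, attribute]

    def X(self) -> np.ndarray:
        """Condition values as a 2-D string array (rows = objects)."""
        return self.data[list(self.condition_attributes)].to_numpy(dtype=object)

    def y(self) -> np.ndarray:
        return self.data[self.decision_attribute].to_numpy(dtype=object)

    # -- encoded view used by the rough-set kernel -------------------------

    def encoded(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
        """Integer-coded condition matrix, per-column cardinalities, decision
        codes and number of decision classes.  Cached; codes follow order of
        first appearance."""
        if "encoded" not in self._cache:
            conds = self.condition_attributes
            n = self.n_objects
            codes = np.empty((n, len(conds)), dtype=np.int64)
            cards = np.empty(len(conds), dtype=np.int64)
            for j, c in enumerate(conds):
                cj, uj = pd.factorize(self.data[c], sort=False)
                codes[:, j] = cj
                cards[j] = len(uj)
            ycodes, yu = pd.factorize(self.data[self.decision_attribute], sort=False)
            self._cache["encoded"] = (
                codes,
                cards,
                ycodes.astype(np.int64),
                len(yu),
            )
        return self._cache["encoded"]

    # -- projection --------------------------------------------------------

    def project(self, subset: Iterable[str]) -> "DecisionTable":
        subset = list(subset)
        if not subset:
            raise TableError("projection subset is empty")
        unknown = [a for a in subset if a not in self.condition_attributes]
        if unknown:
            raise TableError(f"unknown attribute(s): {unknown}")
        keep = [c for c in self.condition_attributes if c in set(subset)]
        return DecisionTable(
            self.data[keep + [self.decision_attribute]], self.decision_attribute
        )

    def write(self, path: str | Path, delimiter: str = ",") -> None:
        self.data.to_csv(path, sep=delimiter, index=False, encoding="utf-8")


def _normalize_integer_token(tok: str) -> str:
    try:
        f = float(tok)
    except ValueError:
        return tok
    if f == int(f):
        return str(int(f))
    return tok


def load_decision_table(
    path: str | Path,
    decision_column: str,
    delimiter: str = ",",
    normalize_integers: bool = False,
) -> DecisionTable:
    """Load a delimited-text decision table.

    All cells are read as categorical tokens ("5" and "5.0" stay distinct
    unless ``normalize_integers``).  Any empty cell is a load error naming
    its row and column; duplicate header names are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise TableError(f"no such file: {path}")
    with open(path, newline="", encoding="utf-8") as fh:
        header = next(csv.reader(fh, delimiter=delimiter), None)
    if header is None:
        raise TableError(f"{path}: empty file")
    if len(header) != len(set(header)):
        dupes = sorted({c for c in header if header.count(c) > 1})
        raise TableError(f"{path}: duplicate column names: {dupes}")
    if decision_column not in header:
        raise TableError(f"{path}: decision column {decision_column!r} not found")
    data = pd.read_csv(
        path, sep=delimiter, dtype=str, keep_default_na=False, encoding="utf-8"
    )
    for col in data.columns:
        empties = np.flatnonzero(data[col].str.strip() == "")
        if empties.size:
            raise TableError(
                f"{path}: empty value at row {int(empties[0]) + 1}, column {col!r}"
            )
    if normalize_integers:
        for col in data.columns:
            data[col] = data[col].map(_normalize_integer_token)
    return DecisionTable(data, decision_column)


def write_decision_table(
    table: DecisionTable, path: str | Path, delimiter: str = ","
) -> None:
    table.write(path, delimiter=delimiter)


def project(table: DecisionTable, subset: Iterable[str]) -> DecisionTable:
    """Restrict ``table`` to ``subset`` of condition attributes (+ decision)."""
    return table.project(subset)


def table_from_arrays(
    X,
    y,
    feature_names: Sequence[str] | None = None,
    decision_name: str = "Result",
) -> DecisionTable:
    """Build a DecisionTable from array-like condition values and labels.

    Used by the sklearn-style estimators; values are stringified tokens.
    """
    if isinstance(X, pd.DataFrame):
        if feature_names is None:
            feature_names = [str(c) for c in X.columns]
        X = X.to_numpy()
    X = np.asarray(X)
    if X.ndim != 2:
        raise TableError("X must be 2-dimensional")
    y = np.asarray(y).ravel()
    if len(y) != len(X):
        raise TableError("X and y length mismatch")
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(X.shape[1])]
    if decision_name in feature_names:
        raise TableError(f"decision name {decision_name!r} collides with a feature")
    frame = pd.DataFrame(
        {name: X[:, j] for j, name in enumerate(feature_names)}
    )
    frame[decision_name] = y
    return DecisionTable(frame, decision_name)
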