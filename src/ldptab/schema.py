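"""Column typing and [-1, 1] normalization for mixed-type tables.

Every value — continuous or categorical — is mapped onto the interval
[-1, 1] before noise is added, and mapped back afterwards.  Continuous
columns use an affine min-max map; categorical columns are encoded onto
an equally spaced grid of ``m`` points spanning [-1, 1] (see
:mod:`ldptab.discretize`).  The schema records the per-column bounds or
ordered label set that make both maps exact and reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ColumnSchema",
    "TableSchema",
    "infer_schema",
    "normalize_value",
    "denormalize_value",
    "normalize_column",
    "denormalize_column",
]


@dataclass(frozen=True)
class ColumnSchema:
    """Typing and domain of a single column.

    Parameters
    ----------
    name
        Column name.
    kind
        ``"continuous"`` or ``"categorical"``.
    lower, upper
        Domain bounds (continuous columns only); values outside are a
        caller error, never silently clamped.
    labels
        Ordered tuple of the ``m >= 2`` distinct category labels
        (categorical columns only).  Position in the tuple defines the
        grid encoding, so the order must be stable across runs.
    """

    name: str
    kind: str
    lower: float | None = None
    upper: float | None = None
    labels: tuple | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"column {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == "continuous":
            if self.lower is None or self.upper is None:
                raise ValueError(f"column {self.name!r}: continuous columns need bounds")
            if not np.isfinite(self.lower) or not np.isfinite(self.upper):
                raise ValueError(f"column {self.name!r}: bounds must be finite")
            if not self.lower < self.upper:
                raise ValueError(
                    f"column {self.name!r}: lower ({self.lower}) must be < upper ({self.upper})"
                )
            if self.labels is not None:
                raise ValueError(f"column {self.name!r}: continuous columns take no labels")
        else:
            if self.labels is None:
                raise ValueError(f"column {self.name!r}: categorical columns need labels")
            object.__setattr__(self, "labels", tuple(self.labels))
            if len(self.labels) < 2:
                raise ValueError(
                    f"column {self.name!r}: needs >= 2 categories, got {len(self.labels)}"
                )
            if len(set(self.labels)) != len(self.labels):
                raise ValueError(f"column {self.name!r}: duplicate category labels")
            if self.lower is not None or self.upper is not None:
                raise ValueError(f"column {self.name!r}: categorical columns take no bounds")

    @property
    def cardinality(self) -> int:
        """Number of categories ``m`` (categorical columns only)."""
        if self.kind != "categorical":
            raise ValueError(f"column {self.name!r} is continuous, has no cardinality")
        return len(self.labels)

    def label_index(self, value) -> int:
        """Position of ``value`` in the ordered label set."""
        try:
            return self.labels.index(value)
        except ValueError:
            raise ValueError(
                f"column {self.name!r}: unknown category {value!r}"
            ) from None

    def to_dict(self) -> dict:
        if self.kind == "continuous":
            return {"name": self.name, "kind": "continuous",
                    "lower": float(self.lower), "upper": float(self.upper)}
        return {"name": self.name, "kind": "categorical", "labels": list(self.labels)}

    @classmethod
    def from_dict(cls, d: dict) -> "ColumnSchema":
        if d.get("kind") == "continuous":
            return cls(name=d["name"], kind="continuous",
                       lower=float(d["lower"]), upper=float(d["upper"]))
        return cls(name=d["name"], kind="categorical", labels=tuple(d["labels"]))


@dataclass(frozen=True)
class TableSchema:
    """Ordered collection of :class:`ColumnSchema` plus an optional outcome column."""

    columns: tuple[ColumnSchema, ...]
    label: str | None = None
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "columns", tuple(self.columns))
        names = [c.name for c in self.columns]
        if len(set(names)) != len(names):
            raise ValueError("duplicate column names in schema")
        if self.label is not None:
            col = self[self.label]
            if col.kind != "categorical":
                raise ValueError(f"label column {self.label!r} must be categorical")

    def __getitem__(self, name: str) -> ColumnSchema:
        for c in self.columns:
            if c.name == name:
                return c
        raise KeyError(f"no column named {name!r} in schema")

    def __contains__(self, name: str) -> bool:
        return any(c.name == name for c in self.columns)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.columns]

    def to_dict(self) -> dict:
        d = {"columns": [c.to_dict() for c in self.columns], "label": self.label}
        if self.metadata:
            d["metadata"] = self.metadata
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TableSchema":
        return cls(
            columns=tuple(ColumnSchema.from_dict(c) for c in d["columns"]),
            label=d.get("label"),
            metadata=d.get("metadata", {}),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TableSchema":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def validate_table(self, table: pd.DataFrame) -> None:
        """Raise if any cell of ``table`` violates this schema."""
        for col in self.columns:
            if col.name not in table.columns:
                raise ValueError(f"table is missing column {col.name!r}")
            s = table[col.name]
            if col.kind == "continuous":
                vals = pd.to_numeric(s, errors="coerce")
                if vals.isna().any():
                    raise ValueError(f"column {col.name!r}: non-numeric or missing value")
                if (vals < col.lower).any() or (vals > col.upper).any():
                    raise ValueError(
                        f"column {col.name!r}: value outside [{col.lower}, {col.upper}]"
                    )
            else:
                bad = ~s.isin(col.labels)
                if bad.any():
                    raise ValueError(
                        f"column {col.name!r}: {s[bad].iloc[0]!r} not in the label set"
                    )


def _sorted_labels(values: Iterable) -> tuple:
    # coerce numpy scalars to plain Python so schemas serialize to JSON
    vals = [v.item() if isinstance(v, np.generic) else v for v in values]
    try:
        return tuple(sorted(vals))  # numeric, or homogeneous text
    except TypeError:
        return tuple(sorted(vals, key=str))


def infer_schema(
    table: pd.DataFrame,
    categorical_columns: Iterable[str] = (),
    label: str | None = None,
    drop_missing: bool = True,
) -> TableSchema:
    """Fit a :class:`TableSchema` to a table.

    Continuous columns get ``lower``/``upper`` equal to the observed
    min/max; categorical columns get their distinct values, ascending.
    Rows with any missing value are removed first (``drop_missing=True``,
    the default) or rejected (``drop_missing=False``).
    """
    categorical = set(categorical_columns)
    if label is not None:
        categorical.add(label)
    unknown = categorical - set(table.columns)
    if unknown:
        raise ValueError(f"categorical columns not in table: {sorted(unknown)}")

    if table.isna().any().any():
        if not drop_missing:
            raise ValueError("table contains missing values and drop_missing=False")
        table = table.dropna(axis=0, how="any")
    if len(table) == 0:
        raise ValueError("table is empty after removal of rows with missing values")

    cols = []
    for name in table.columns:
        s = table[name]
        if name in categorical:
            labels = _sorted_labels(s.unique())
            if len(labels) < 2:
                raise ValueError(
                    f"categorical column {name!r} has a single distinct value; "
                    "it cannot be perturbed meaningfully"
                )
            cols.append(ColumnSchema(name=name, kind="categorical", labels=labels))
        else:
            vals = pd.to_numeric(s, errors="coerce")
            if vals.isna().any():
                raise ValueError(f"non-numeric value in continuous column {name!r}")
            lo, hi = float(vals.min()), float(vals.max())
            if lo == hi:
                raise ValueError(
                    f"continuous column {name!r} is constant; bounds would be degenerate"
                )
            cols.append(ColumnSchema(name=name, kind="continuous", lower=lo, upper=hi))
    return TableSchema(columns=tuple(cols), label=label)


def normalize_value(x, schema: ColumnSchema) -> float:
    """Map a raw value into [-1, 1].

    Continuous: the affine map ``2 (x - lower) / (upper - lower) - 1``.
    Categorical: the grid point ``-1 + 2 j / (m - 1)`` of the label's
    position ``j`` in the ordered label set.
    """
    if schema.kind == "continuous":
        if not schema.lower <= x <= schema.upper:
            raise ValueError(
                f"column {schema.name!r}: {x} outside [{schema.lower}, {schema.upper}]"
            )
        return 2.0 * (x - schema.lower) / (schema.upper - schema.lower) - 1.0
    j = schema.label_index(x)
    return -1.0 + 2.0 * j / (schema.cardinality - 1)


def denormalize_value(y: float, schema: ColumnSchema):
    """Exact inverse of :func:`normalize_value` on [-1, 1].

    Continuous columns invert the affine map; categorical columns decode
    to the nearest grid point's label.
    """
    if not -1.0 <= y <= 1.0:
        raise ValueError(f"column {schema.name!r}: {y} outside [-1, 1]")
    if schema.kind == "continuous":
        return schema.lower + (y + 1.0) * (schema.upper - schema.lower) / 2.0
    m = schema.cardinality
    j = int(round((y + 1.0) * (m - 1) / 2.0))
    return schema.labels[min(max(j, 0), m - 1)]


def normalize_column(values: Sequence, schema: ColumnSchema) -> np.ndarray:
    """Vectorized :func:`normalize_value` over a column."""
    if schema.kind == "continuous":
        x = np.asarray(values, dtype=float)
        if np.any(x < schema.lower) or np.any(x > schema.upper):
            raise ValueError(
                f"column {schema.name!r}: value outside [{schema.lower}, {schema.upper}]"
            )
        return 2.0 * (x - schema.lower) / (schema.upper - schema.lower) - 1.0
    idx = np.array([schema.label_index(v) for v in values], dtype=float)
    return -1.0 + 2.0 * idx / (schema.cardinality - 1)


def denormalize_column(y: Sequence, schema: ColumnSchema):
    """Vectorized :func:`denormalize_value` over a column."""
    y = np.asarray(y, dtype=float)
    if np.any(y < -1.0) or np.any(y > 1.0):
        raise ValueError(f"column {schema.name!r}: value outside [-1, 1]")
    if schema.kind == "continuous":
        return schema.lower + (y + 1.0) * (schema.upper - schema.lower) / 2.0
    m = schema.cardinality
    j = np.clip(np.rint((y + 1.0) * (m - 1) / 2.0).astype(int), 0, m - 1)
    return np.array([schema.labels[i] for i in j], dtype=object)
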