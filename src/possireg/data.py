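"""Clinical observation tables and dummy encoding.

A study table holds one continuous response, any number of continuous
predictors, and (at most) one categorical predictor stored as ordered
integer codes.  A categorical predictor with ``a`` levels enters the
design matrix as ``a - 1`` binary indicator columns; the reference level
maps to the all-zero indicator pattern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "VariableSpec",
    "ObservationTable",
    "DesignMatrix",
    "TRIGLYCERIDE_SPEC",
    "load_table",
    "encode_dummies",
    "decode_indicators",
    "ValidationError",
    "EmptyDataError",
    "ConfigurationError",
]


class ValidationError(ValueError):
    """A row violates the declared variable specification."""


class EmptyDataError(ValueError):
    """No valid rows remain after validation."""


class ConfigurationError(ValueError):
    """An operation was configured inconsistently with the data."""


@dataclass(frozen=True)
class VariableSpec:
    """Metadata for one column of a study table.

    Parameters
    ----------
    name : str
        Column label, matching the CSV header.
    role : {"response", "continuous", "categorical"}
        Statistical role of the variable.
    levels : tuple of int, optional
        Ordered category codes (categorical variables only).
    level_labels : tuple of str, optional
        Human-readable names per level; indicator columns for non-reference
        levels take these names (e.g. ``Border``, ``Hyper``).
    units : str
        Free-text measurement units.
    """

    name: str
    role: str
    levels: tuple[int, ...] | None = None
    level_labels: tuple[str, ...] | None = None
    units: str = ""

    def __post_init__(self) -> None:
        if self.role not in ("response", "continuous", "categorical"):
            raise ConfigurationError(f"unknown role {self.role!r} for {self.name!r}")
        if self.role == "categorical":
            if not self.levels:
                raise ConfigurationError(f"categorical {self.name!r} needs levels")
            if len(set(self.levels)) != len(self.levels):
                raise ConfigurationError(f"duplicate levels in {self.name!r}")
            if self.level_labels is not None and len(self.level_labels) != len(self.levels):
                raise ConfigurationError(
                    f"{self.name!r}: {len(self.level_labels)} labels for {len(self.levels)} levels"
                )
        elif self.levels is not None:
            raise ConfigurationError(f"{self.role} variable {self.name!r} must not declare levels")


#: Schema of the triglyceride study table: response in mg/dL, waist
#: circumference in cm, HDL cholesterol in mg/dL, and a three-level
#: blood-pressure status code (0 normal, 1 borderline, 2 high).
TRIGLYCERIDE_SPEC: tuple[VariableSpec, ...] = (
    VariableSpec("Trig", "response", units="mg/dL"),
    VariableSpec("Waist", "continuous", units="cm"),
    VariableSpec("HDL", "continuous", units="mg/dL"),
    VariableSpec(
        "BloodPressure",
        "categorical",
        levels=(0, 1, 2),
        level_labels=("Normal", "Border", "Hyper"),
    ),
)


def _check_specs(specs: tuple[VariableSpec, ...]) -> None:
    n_resp = sum(1 for s in specs if s.role == "response")
    if n_resp != 1:
        raise ConfigurationError(f"exactly one response variable required, got {n_resp}")


@dataclass(frozen=True)
class ObservationTable:
    """A validated rectangular table of patient records."""

    specs: tuple[VariableSpec, ...]
    data: pd.DataFrame = field(repr=False)
    n_dropped: int = 0

    def __post_init__(self) -> None:
        _check_specs(self.specs)
        names = [s.name for s in self.specs]
        if list(self.data.columns) != names:
            raise ValidationError(
                f"columns {list(self.data.columns)} do not match spec names {names}"
            )
        if self.data.isna().any().any():
            raise ValidationError("table contains missing values after validation")
        for s in self.specs:
            if s.role == "categorical":
                bad = ~self.data[s.name].isin(s.levels)
                if bad.any():
                    row = int(np.flatnonzero(bad.to_numpy())[0])
                    val = self.data[s.name].iloc[row]
                    raise ValidationError(
                        f"row {row}: category code {val!r} not in declared levels "
                        f"{list(s.levels)} of {s.name!r}"
                    )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def response_name(self) -> str:
        return next(s.name for s in self.specs if s.role == "response")

    @property
    def continuous_names(self) -> list[str]:
        return [s.name for s in self.specs if s.role == "continuous"]

    @property
    def categorical_specs(self) -> list[VariableSpec]:
        return [s for s in self.specs if s.role == "categorical"]

    def to_csv(self, path) -> None:
        """Write the table in the same comma-separated dialect ``load_table`` reads."""
        self.data.to_csv(path, index=False)


@dataclass(frozen=True)
class DesignMatrix:
    """Numeric design matrix after dummy encoding.

    ``columns`` starts with ``Intercept`` (all ones), then continuous
    predictors in spec order, then indicator columns in level order.
    ``groups`` maps each predictor block (a continuous variable, or one
    categorical variable) to the design columns it owns, so downstream
    subset selection can move a categorical variable's indicators as one
    unit.
    """

    columns: tuple[str, ...]
    X: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    response_name: str
    groups: dict[str, tuple[str, ...]] = field(default_factory=dict)
    reference_levels: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.X.shape != (len(self.y), len(self.columns)):
            raise ValidationError(
                f"matrix shape {self.X.shape} inconsistent with "
                f"{len(self.columns)} columns and {len(self.y)} responses"
            )
        if not np.all(self.X[:, 0] == 1.0):
            raise ValidationError("intercept column must be all ones")

    @property
    def n_rows(self) -> int:
        return len(self.y)

    def column_index(self, label: str) -> int:
        try:
            return self.columns.index(label)
        except ValueError:
            raise ConfigurationError(f"unknown column {label!r}") from None

    def subset(self, group_names: list[str] | tuple[str, ...]) -> "DesignMatrix":
        """Design matrix restricted to the intercept plus the given predictor blocks."""
        cols = ["Intercept"]
        groups: dict[str, tuple[str, ...]] = {}
        for g in group_names:
            if g not in self.groups:
                raise ConfigurationError(f"unknown predictor block {g!r}")
            cols.extend(self.groups[g])
            groups[g] = self.groups[g]
        idx = [self.column_index(c) for c in cols]
        return DesignMatrix(
            columns=tuple(cols),
            X=self.X[:, idx],
            y=self.y,
            response_name=self.response_name,
            groups=groups,
            reference_levels=dict(self.reference_levels),
        )

    def take_rows(self, idx: np.ndarray) -> "DesignMatrix":
        return DesignMatrix(
            columns=self.columns,
            X=self.X[idx],
            y=self.y[idx],
            response_name=self.response_name,
            groups=dict(self.groups),
            reference_levels=dict(self.reference_levels),
        )


def load_table(path, specs: tuple[VariableSpec, ...] = TRIGLYCERIDE_SPEC) -> ObservationTable:
    """Read a CSV of patient records and validate it against ``specs``.

    Rows with missing cells are dropped and counted; a category code
    outside the declared levels raises :class:`ValidationError` naming
    the offending row and value.
    """
    _check_specs(specs)
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise ValidationError(f"could not read {path}: {exc}") from exc

    names = [s.name for s in specs]
    if list(df.columns) != names:
        raise ValidationError(f"header {list(df.columns)} does not match spec names {names}")

    n_before = len(df)
    df = df.dropna().reset_index(drop=True)
    n_dropped = n_before - len(df)
    if n_dropped:
        logger.info("dropped %d row(s) with missing values from %s", n_dropped, path)
    if len(df) == 0:
        raise EmptyDataError(f"no valid rows in {path}")
    df = df.astype({s.name: (int if s.role == "categorical" else float) for s in specs})
    return ObservationTable(specs=tuple(specs), data=df[names], n_dropped=n_dropped)


def encode_dummies(table: ObservationTable, reference_level: int = 0) -> DesignMatrix:
    """Dummy-encode the table: ``a - 1`` 0/1 indicators per categorical variable.

    The reference level maps to all-zero indicators.  Column order is
    Intercept, continuous variables in spec order, indicator columns in
    declared level order.
    """
    m = len(table)
    cols: list[str] = ["Intercept"]
    arrays: list[np.ndarray] = [np.ones(m)]
    groups: dict[str, tuple[str, ...]] = {}
    ref_levels: dict[str, int] = {}

    for s in table.specs:
        if s.role == "continuous":
            cols.append(s.name)
            arrays.append(table.data[s.name].to_numpy(dtype=float))
            groups[s.name] = (s.name,)

    for s in table.categorical_specs:
        if reference_level not in s.levels:
            raise ConfigurationError(
                f"reference level {reference_level} not among declared levels "
                f"{list(s.levels)} of {s.name!r}"
            )
        ref_levels[s.name] = reference_level
        codes = table.data[s.name].to_numpy()
        block: list[str] = []
        for i, level in enumerate(s.levels):
            if level == reference_level:
                continue
            label = s.level_labels[i] if s.level_labels else f"{s.name}={level}"
            cols.append(label)
            arrays.append((codes == level).astype(float))
            block.append(label)
        groups[s.name] = tuple(block)

    return DesignMatrix(
        columns=tuple(cols),
        X=np.column_stack(arrays),
        y=table.data[table.response_name].to_numpy(dtype=float),
        response_name=table.response_name,
        groups=groups,
        reference_levels=ref_levels,
    )


def decode_indicators(matrix: DesignMatrix, table_spec: VariableSpec) -> np.ndarray:
    """Recover original category codes from a design matrix's indicator block.

    Inverse of :func:`encode_dummies` for one categorical variable; rows
    with all-zero indicators map to the reference level.
    """
    ref = matrix.reference_levels.get(table_spec.name)
    if ref is None:
        raise ConfigurationError(f"{table_spec.name!r} was not encoded in this matrix")
    block = matrix.groups[table_spec.name]
    codes = np.full(matrix.n_rows, ref)
    non_ref = [lv for lv in table_spec.levels if lv != ref]
    for label, level in zip(block, non_ref):
        col = matrix.X[:, matrix.column_index(label)]
        codes[col == 1.0] = level
    return codes
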