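"""Data model, CSV I/O, dataset splitting and experiment configuration.

The central container is :class:`FeatureTable`: a numeric feature matrix
(rows = subjects) together with an outcome column taking the values
``"positive"`` (the rare event, severe hypoglycemia), ``"negative"`` or
``"unknown"``.  Rows whose outcome is ``"unknown"`` form the unlabeled set
used by the semi-supervised routines.

All splitting operations are pure functions of ``(table, parameters, seed)``;
no global random state is consulted.  Feature order is the column order of
the source file and is preserved through every operation so that downstream
tie-breaking is reproducible.
"""

from __future__ import annotations

import io
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import (
    ConfigurationError,
    ParseError,
    SchemaError,
    StratificationError,
    ValidationError,
)

logger = logging.getLogger(__name__)

POSITIVE = "positive"
NEGATIVE = "negative"
UNKNOWN = "unknown"
OUTCOMES = (POSITIVE, NEGATIVE, UNKNOWN)

#: default encodings accepted for each outcome on CSV ingest
DEFAULT_OUTCOME_CODES: Mapping[str, tuple[str, ...]] = {
    POSITIVE: ("1", "positive", "SH", "sh"),
    NEGATIVE: ("0", "negative", "nonSH", "non-SH", "nonsh"),
    UNKNOWN: ("", "NA", "na", "NaN", "nan", "unknown", "Unknown", "?"),
}


@dataclass
class CsvDialect:
    """CSV ingest options: outcome column name and outcome-code mapping."""

    outcome_column: str = "outcome"
    id_column: str | None = "subject_id"
    outcome_codes: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_CODES)
    )
    sep: str = ","


@dataclass
class FeatureTable:
    """Feature matrix plus outcome labels, aligned on a shared index.

    Parameters
    ----------
    data:
        Numeric features; the index is the (opaque) subject identifier.
    outcome:
        Series aligned with ``data.index`` holding ``"positive"``,
        ``"negative"`` or ``"unknown"``.
    """

    data: pd.DataFrame
    outcome: pd.Series

    def __post_init__(self) -> None:
        if not self.data.index.equals(self.outcome.index):
            self.outcome = self.outcome.reindex(self.data.index)
        bad = set(self.outcome.unique()) - set(OUTCOMES)
        if bad:
            raise ValidationError(f"invalid outcome values: {sorted(bad)}")
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise SchemaError(f"duplicate feature names: {dupes}")

    # -- basic accessors -------------------------------------------------
    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_rows(self) -> int:
        return len(self.data)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def index(self) -> pd.Index:
        return self.data.index

    def class_counts(self) -> dict[str, int]:
        vc = self.outcome.value_counts()
        return {k: int(vc.get(k, 0)) for k in OUTCOMES}

    # -- subsetting ------------------------------------------------------
    def subset(self, index: Iterable) -> "FeatureTable":
        """Rows with the given index labels, in the given order."""
        idx = pd.Index(index)
        return FeatureTable(self.data.loc[idx], self.outcome.loc[idx])

    def labeled(self) -> "FeatureTable":
        mask = self.outcome != UNKNOWN
        return FeatureTable(self.data.loc[mask], self.outcome.loc[mask])

    def unlabeled(self) -> "FeatureTable":
        mask = self.outcome == UNKNOWN
        return FeatureTable(self.data.loc[mask], self.outcome.loc[mask])

    def with_outcome(self, outcome: pd.Series | str) -> "FeatureTable":
        if isinstance(outcome, str):
            outcome = pd.Series(outcome, index=self.data.index)
        return FeatureTable(self.data.copy(), outcome.reindex(self.data.index))

    def concat(self, other: "FeatureTable") -> "FeatureTable":
        if list(other.feature_names) != self.feature_names:
            raise SchemaError("cannot concatenate tables with different features")
        overlap = self.index.intersection(other.index)
        if len(overlap):
            raise ValidationError(f"row index overlap on concat: {list(overlap[:5])}")
        return FeatureTable(
            pd.concat([self.data, other.data]),
            pd.concat([self.outcome, other.outcome]),
        )

    # -- numeric views ---------------------------------------------------
    def X(self, features: Sequence[str] | None = None) -> np.ndarray:
        cols = list(features) if features is not None else self.feature_names
        missing = [c for c in cols if c not in self.data.columns]
        if missing:
            raise SchemaError(f"unknown features requested: {missing}")
        return self.data[cols].to_numpy(dtype=float)

    def y01(self) -> np.ndarray:
        """Outcome as 0/1 (positive = 1); raises if any row is unlabeled."""
        if (self.outcome == UNKNOWN).any():
            raise ValidationError("y01 requested on a table with unknown outcomes")
        return (self.outcome == POSITIVE).to_numpy(dtype=int)

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.data.copy(), self.outcome.copy())


@dataclass(frozen=True)
class ViewSpec:
    """Disjoint partition of feature names into two views.

    View 1 conventionally holds the glycemic variables and view 2 the
    management/medication variables, but any disjoint non-empty split works.
    """

    view1: tuple[str, ...]
    view2: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "view1", tuple(self.view1))
        object.__setattr__(self, "view2", tuple(self.view2))
        if not self.view1 or not self.view2:
            raise ValidationError("both views must be non-empty")
        overlap = set(self.view1) & set(self.view2)
        if overlap:
            raise ValidationError(f"views overlap on: {sorted(overlap)}")

    def validate_against(self, table: FeatureTable) -> None:
        missing = [f for f in self.view1 + self.view2 if f not in table.feature_names]
        if missing:
            raise SchemaError(f"view features absent from table: {missing}")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"view1": list(self.view1), "view2": list(self.view2)}, fh)

    @classmethod
    def from_yaml(cls, path) -> "ViewSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        try:
            return cls(tuple(raw["view1"]), tuple(raw["view2"]))
        except (KeyError, TypeError) as exc:
            raise SchemaError(f"view file {path} lacks view1/view2 lists") from exc


@dataclass
class SplitResult:
    train: FeatureTable
    test: FeatureTable
    seed: int


LEARNER_NAMES = ("LR", "XGBoost", "NB", "SVM", "RF")
SELECTION_METHODS = ("MD", "LASSO", "Boruta", "MRMR", "consensus")


@dataclass
class ExperimentConfig:
    """Shared experiment settings: split fraction, CV folds, learner, selector."""

    split_fraction: float = 0.20
    cv_folds: int = 5
    learner: str = "RF"
    selection: str = "MD"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.split_fraction < 1:
            raise ConfigurationError("split_fraction must be in (0, 1)")
        if self.cv_folds < 2:
            raise ConfigurationError("cv_folds must be >= 2")
        if self.learner not in LEARNER_NAMES:
            raise ConfigurationError(
                f"unknown learner {self.learner!r}; expected one of {LEARNER_NAMES}"
            )
        if self.selection not in SELECTION_METHODS:
            raise ConfigurationError(
                f"unknown selection {self.selection!r}; expected one of {SELECTION_METHODS}"
            )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _normalise_code(value) -> str:
    """Render a raw CSV cell as a canonical code string ('1.0' -> '1')."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    s = str(value).strip()
    if s.endswith(".0") and s[:-2].lstrip("-").isdigit():
        s = s[:-2]
    return s


def parse_outcome(value, codes: Mapping[str, tuple[str, ...]] = DEFAULT_OUTCOME_CODES) -> str:
    s = _normalise_code(value)
    for label, accepted in codes.items():
        if s in accepted:
            return label
    raise ParseError(f"unrecognised outcome code {value!r}")


def load_table(path, dialect: CsvDialect | None = None) -> FeatureTable:
    """Read a feature table from CSV.

    The outcome column (named in the dialect, default ``outcome``) is parsed
    to positive/negative/unknown; every other column (bar the optional id
    column) must be numeric.  Non-numeric feature cells raise a
    :class:`ParseError` naming the row and column.
    """
    dialect = dialect or CsvDialect()
    try:
        raw = pd.read_csv(path, sep=dialect.sep, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc
    if dialect.outcome_column not in raw.columns:
        raise SchemaError(
            f"{path}: missing outcome column {dialect.outcome_column!r} "
            f"(found {list(raw.columns)})"
        )
    if dialect.id_column and dialect.id_column in raw.columns:
        raw = raw.set_index(dialect.id_column)
    outcome = raw[dialect.outcome_column].map(
        lambda v: parse_outcome(v, dialect.outcome_codes)
    )
    feats = raw.drop(columns=[dialect.outcome_column])
    parsed = {}
    for col in feats.columns:
        values = feats[col].replace("", np.nan)
        numeric = pd.to_numeric(values, errors="coerce")
        bad = numeric.isna() & values.notna()
        if bad.any():
            row = feats.index[bad.to_numpy().nonzero()[0][0]]
            raise ParseError(
                f"{path}: non-numeric value {feats.loc[row, col]!r} "
                f"in row {row!r}, column {col!r}"
            )
        parsed[col] = numeric
    return FeatureTable(pd.DataFrame(parsed, index=feats.index), outcome)


def save_table(table: FeatureTable, path, dialect: CsvDialect | None = None) -> None:
    """Write a feature table to CSV (full float precision round-trips)."""
    dialect = dialect or CsvDialect()
    out = table.data.copy()
    out[dialect.outcome_column] = table.outcome.map(
        {POSITIVE: "1", NEGATIVE: "0", UNKNOWN: "NA"}
    )
    out.index.name = dialect.id_column or "subject_id"
    out.to_csv(path, sep=dialect.sep, float_format="%.17g")


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def split_train_test(table: FeatureTable, fraction: float = 0.20, seed: int = 0) -> SplitResult:
    """Stratified train/test split of the labeled rows.

    The overall test size is ``round(fraction * N)`` (half-up).  Per class the
    target is the half-up rounding of the proportional share; any residual is
    absorbed by the majority class, so the per-class deviation from the
    stratified ideal never exceeds one row.
    """
    if not 0 < fraction < 1:
        raise ConfigurationError("fraction must be in (0, 1)")
    labeled = table.labeled()
    counts = labeled.class_counts()
    for cls in (POSITIVE, NEGATIVE):
        if counts[cls] < 2:
            raise StratificationError(
                f"class {cls!r} has {counts[cls]} rows; need >= 2 to stratify"
            )
    n_total = labeled.n_rows
    n_test = _round_half_up(fraction * n_total)
    per_class = {
        cls: _round_half_up(fraction * counts[cls]) for cls in (POSITIVE, NEGATIVE)
    }
    majority = max((POSITIVE, NEGATIVE), key=lambda c: counts[c])
    per_class[majority] += n_test - sum(per_class.values())

    rng = np.random.default_rng(seed)
    test_labels: list = []
    for cls in (POSITIVE, NEGATIVE):
        cls_index = labeled.index[(labeled.outcome == cls).to_numpy()]
        chosen = rng.permutation(len(cls_index))[: per_class[cls]]
        test_labels.extend(cls_index[np.sort(chosen)])
    test_set = set(test_labels)
    train_index = [i for i in labeled.index if i not in test_set]
    test_index = [i for i in labeled.index if i in test_set]
    result = SplitResult(
        train=labeled.subset(train_index), test=labeled.subset(test_index), seed=seed
    )
    logger.info(
        "split: N=%d, test=%d, per-class test counts=%s, seed=%d",
        n_total, n_test, per_class, seed,
    )
    return result


def kfold_indices(table: FeatureTable, folds: int = 5, seed: int = 0) -> list[np.ndarray]:
    """Stratified k-fold partition of the labeled rows (row positions).

    Fold sizes differ by at most one, both overall and within each class:
    per-class shuffled indices are dealt round-robin, with each class
    starting where the previous one stopped so remainders do not pile up
    on the low-numbered folds.
    """
    labeled = table.labeled()
    n = labeled.n_rows
    if folds < 2:
        raise ConfigurationError("folds must be >= 2")
    if folds > n:
        raise ConfigurationError(f"folds={folds} exceeds row count {n}")
    rng = np.random.default_rng(seed)
    assignments = np.empty(n, dtype=int)
    start = 0
    outcome = labeled.outcome.to_numpy()
    for cls in (POSITIVE, NEGATIVE):
        pos = np.nonzero(outcome == cls)[0]
        if len(pos) == 0:
            continue
        shuffled = pos[rng.permutation(len(pos))]
        for i, row in enumerate(shuffled):
            assignments[row] = (start + i) % folds
        start = (start + len(pos)) % folds
    return [np.nonzero(assignments == f)[0] for f in range(folds)]
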