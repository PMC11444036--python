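"""Imputation, longitudinal summarization and majority-class under-sampling.

Longitudinal raw variables (e.g. HbA1c measured at successive visits) are
imputed with last-observation-carried-forward (LOCF) and then collapsed to
per-subject summary statistics — mean and sample standard deviation for the
continuous clinical variables, mean alone for the binary medication
indicators (yielding a use-fraction in [0, 1]).  Non-longitudinal columns
use median imputation.  Under-sampling randomly drops majority-class rows
to a target majority-per-minority ratio; it is the imbalance treatment used
ahead of every model fit inside co-training.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_data import NEGATIVE, POSITIVE, UNKNOWN, FeatureTable
from .exceptions import ConfigurationError, ImputationError, SchemaError

logger = logging.getLogger(__name__)

#: the 12 expert-selected raw variables and the statistics computed from each.
#: Five continuous clinical variables contribute mean and standard deviation;
#: seven medication indicators contribute a mean only — 17 columns in total.
MD_SCHEMA: Mapping[str, tuple[str, ...]] = {
    "hba1c": ("mean", "std"),
    "fpg": ("mean", "std"),
    "g1check": ("mean", "std"),
    "g1diabed": ("mean", "std"),
    "g1nutrit": ("mean", "std"),
    "sulfonylurea": ("mean",),
    "meglitinide": ("mean",),
    "nphl_insulin": ("mean",),
    "reg_insulin": ("mean",),
    "la_insulin": ("mean",),
    "othbol_insulin": ("mean",),
    "premix_insulin": ("mean",),
}


def locf_impute(series: Sequence[float], fallback: float | None = None) -> np.ndarray:
    """Last-observation-carried-forward over a visit-ordered series.

    Missing entries take the most recent preceding observed value.  Leading
    missing entries (no prior observation) take the subject's observed
    median for the variable; an all-missing series takes ``fallback``
    (typically the cohort median) or raises if none is given.  Observed
    values are never altered.
    """
    arr = np.asarray(series, dtype=float)
    observed = arr[~np.isnan(arr)]
    if observed.size == 0:
        if fallback is None or math.isnan(fallback):
            raise ImputationError("all-missing series and no fallback value")
        return np.full(arr.shape, float(fallback))
    filled = pd.Series(arr).ffill().to_numpy()
    leading = np.isnan(filled)
    if leading.any():
        filled[leading] = float(np.median(observed))
    return filled


def median_impute(column: Sequence[float]) -> np.ndarray:
    """Replace missing entries with the median of the observed entries."""
    arr = np.asarray(column, dtype=float)
    observed = arr[~np.isnan(arr)]
    if observed.size == 0:
        raise ImputationError("fully missing column")
    out = arr.copy()
    out[np.isnan(out)] = float(np.median(observed))
    return out


def impute_panel(panel: pd.DataFrame, variables: Sequence[str] | None = None) -> pd.DataFrame:
    """LOCF-impute every variable of a longitudinal panel, per subject.

    ``panel`` has columns ``subject_id``, ``visit`` and one column per raw
    variable; rows are sorted by visit within subject before carrying
    forward.  Subjects with no observation at all for a variable fall back
    to the cohort median of that variable.
    """
    if variables is None:
        variables = [c for c in panel.columns if c not in ("subject_id", "visit")]
    missing = [v for v in variables if v not in panel.columns]
    if missing:
        raise SchemaError(f"panel lacks variables: {missing}")
    out = panel.sort_values(["subject_id", "visit"]).reset_index(drop=True)
    for var in variables:
        col = out[var].to_numpy(dtype=float)
        observed = col[~np.isnan(col)]
        if observed.size == 0:
            raise ImputationError(f"variable {var!r} has no observed value in the cohort")
        cohort_median = float(np.median(observed))
        filled = np.empty_like(col)
        for _, idx in out.groupby("subject_id", sort=False).indices.items():
            filled[idx] = locf_impute(col[idx], fallback=cohort_median)
        out[var] = filled
    return out


def summarize_longitudinal(
    panel: pd.DataFrame,
    schema: Mapping[str, Sequence[str]] = MD_SCHEMA,
) -> pd.DataFrame:
    """Collapse an imputed panel to per-subject summary features.

    For each variable the schema names the statistics to compute over the
    subject's visits: ``mean`` and/or ``std``.  The standard deviation uses
    the n−1 denominator; a single visit yields std = 0 so downstream models
    never see a missing summary.  Output columns are named
    ``{variable}_{statistic}`` in schema order; the 12-variable default
    schema yields 17 columns.
    """
    missing = [v for v in schema if v not in panel.columns]
    if missing:
        raise SchemaError(f"schema variables absent from panel: {missing}")
    if panel[list(schema)].isna().any().any():
        raise ImputationError("panel contains missing values; impute before summarizing")
    grouped = panel.groupby("subject_id", sort=False)
    out = {}
    for var, stats in schema.items():
        for stat in stats:
            if stat == "mean":
                out[f"{var}_mean"] = grouped[var].mean()
            elif stat == "std":
                std = grouped[var].std(ddof=1)
                out[f"{var}_std"] = std.fillna(0.0)
            else:
                raise SchemaError(f"unknown statistic {stat!r} for variable {var!r}")
    return pd.DataFrame(out)


def undersample(table: FeatureTable, ratio: float = 1.0, seed: int = 0) -> FeatureTable:
    """Randomly down-sample the majority class of the labeled rows.

    All minority rows are kept; majority rows are drawn without replacement
    down to ``ceil(ratio * minority_count)`` (or all of them if fewer).
    Unknown-outcome rows pass through untouched.  Row order of the source
    table is preserved.
    """
    if ratio < 1:
        raise ConfigurationError(f"ratio must be >= 1, got {ratio}")
    counts = table.class_counts()
    if counts[POSITIVE] == 0 or counts[NEGATIVE] == 0:
        raise ConfigurationError("both classes must be present to under-sample")
    minority, majority = (
        (POSITIVE, NEGATIVE) if counts[POSITIVE] <= counts[NEGATIVE] else (NEGATIVE, POSITIVE)
    )
    n_keep = min(counts[majority], math.ceil(ratio * counts[minority]))
    rng = np.random.default_rng(seed)
    majority_index = table.index[(table.outcome == majority).to_numpy()]
    kept = set(majority_index[np.sort(rng.permutation(len(majority_index))[:n_keep])])
    keep_mask = [
        (o != majority) or (i in kept) for i, o in zip(table.index, table.outcome)
    ]
    result = table.subset(table.index[keep_mask])
    logger.info(
        "undersample: %s %d -> %d (ratio %.2f, minority %d), seed=%d",
        majority, counts[majority], n_keep, ratio, counts[minority], seed,
    )
    return result
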