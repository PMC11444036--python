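"""Confusion-matrix metrics, percentage improvement, and pipeline reports.

The positive class is the rare event (severe hypoglycemia) throughout.  Six
metrics are derived from the confusion matrix:

    PPV  = TP / (TP + FP)          NPV  = TN / (TN + FN)
    Sens = TP / (TP + FN)          Spec = TN / (TN + FP)
    Acc  = (TP + TN) / total       F1   = 2·PPV·Sens / (PPV + Sens)

A metric with a zero denominator is *undefined* and carried as an explicit
marker (``None`` in memory, ``"undef"`` in CSV output) — never silently
coerced to 0, since near-degenerate classifiers on imbalanced data are a
reportable outcome, not an error.  Reports print at three decimals but full
precision is preserved in memory and JSON, because per-iteration percentage
improvements computed from rounded values drift from those computed from
full-precision values.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_data import FeatureTable, ViewSpec
from .cotraining import (
    BaseLearner,
    CoTrainConfig,
    SelfTrainConfig,
    combine_views,
    cotrain_multiview,
    make_learner,
    self_train,
)
from .exceptions import ValidationError

logger = logging.getLogger(__name__)

UNDEF = "undef"
METRIC_NAMES = ("NPV", "PPV", "specificity", "sensitivity", "accuracy", "F1")


@dataclass(frozen=True)
class ConfusionMatrix:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValidationError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class MetricsReport:
    """Six derived metrics; ``None`` marks an undefined (0/0) value."""

    NPV: float | None
    PPV: float | None
    specificity: float | None
    sensitivity: float | None
    accuracy: float | None
    F1: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in METRIC_NAMES}

    def formatted(self, decimals: int = 3) -> dict[str, str]:
        return {
            k: (UNDEF if v is None else f"{v:.{decimals}f}")
            for k, v in self.as_dict().items()
        }


def confusion(pred: Sequence, truth: Sequence) -> ConfusionMatrix:
    """Tally a confusion matrix; accepts 0/1 or positive/negative labels."""
    p = _as01(pred, "pred")
    t = _as01(truth, "truth")
    if p.shape != t.shape:
        raise ValidationError(f"length mismatch: {p.shape} vs {t.shape}")
    return ConfusionMatrix(
        TP=int(np.sum((p == 1) & (t == 1))),
        FP=int(np.sum((p == 1) & (t == 0))),
        TN=int(np.sum((p == 0) & (t == 0))),
        FN=int(np.sum((p == 0) & (t == 1))),
    )


def _as01(labels: Sequence, what: str) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "OU":
        mapping = {"positive": 1, "negative": 0, "1": 1, "0": 0}
        try:
            arr = np.array([mapping[str(v)] for v in arr])
        except KeyError as exc:
            raise ValidationError(f"unknown label {exc.args[0]!r} in {what}") from exc
    arr = arr.astype(int)
    if not np.isin(arr, (0, 1)).all():
        raise ValidationError(f"{what} labels must be binary")
    return arr


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """The six confusion-matrix metrics, with undefined markers for 0/0."""
    if cm.total == 0:
        raise ValidationError("empty confusion matrix")
    ppv = _ratio(cm.TP, cm.TP + cm.FP)
    sens = _ratio(cm.TP, cm.TP + cm.FN)
    if ppv is None or sens is None or ppv + sens == 0:
        f1 = None
    else:
        f1 = 2 * ppv * sens / (ppv + sens)
    return MetricsReport(
        NPV=_ratio(cm.TN, cm.TN + cm.FN),
        PPV=ppv,
        specificity=_ratio(cm.TN, cm.TN + cm.FP),
        sensitivity=sens,
        accuracy=(cm.TP + cm.TN) / cm.total,
        F1=f1,
    )


def f1_score(ppv: float, sensitivity: float) -> float | None:
    """Harmonic mean of PPV and sensitivity (None when both are zero)."""
    if ppv + sensitivity == 0:
        return None
    return 2 * ppv * sensitivity / (ppv + sensitivity)


def percentage_improvement(first: float, last: float) -> float | None:
    """Signed percentage change from the first to the last iteration value.

    ``(last − first) × 100 / first``; undefined (None) when ``first`` is 0.
    """
    if first == 0:
        return None
    return (last - first) * 100.0 / first


@dataclass
class ImprovementRecord:
    first: MetricsReport
    last: MetricsReport

    def percentages(self) -> dict[str, float | None]:
        out = {}
        for name in METRIC_NAMES:
            a, b = getattr(self.first, name), getattr(self.last, name)
            out[name] = None if a is None or b is None else percentage_improvement(a, b)
        return out


# ---------------------------------------------------------------------------
# Pipeline evaluation
# ---------------------------------------------------------------------------

def evaluate_learner(
    learner: BaseLearner, test: FeatureTable, features: Sequence[str] | None = None
) -> MetricsReport:
    pred = learner.predict(test.X(features))
    return metrics(confusion(pred, test.y01()))


def evaluate_pipeline(
    train: FeatureTable,
    test: FeatureTable,
    learners: Sequence[str] = ("LR", "XGBoost", "NB", "SVM", "RF"),
    selections: dict[str, Sequence[str]] | None = None,
    methods: Sequence[str] = ("conventional",),
    unlabeled: FeatureTable | None = None,
    views: ViewSpec | None = None,
    cotrain_config: CoTrainConfig | None = None,
    selftrain_config: SelfTrainConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Run methods × learners × feature selections and tabulate the metrics.

    ``selections`` maps a selection name (e.g. ``"MD"``, ``"MRMR"``) to the
    feature list it produces; ``None`` evaluates all features under the name
    ``"all"``.  Methods: ``conventional`` (supervised fit on the training
    set), ``selftrain`` (single-view co-training), and ``cotrain-AND`` /
    ``cotrain-OR`` (two-view co-training, combined predictions); the latter
    require ``unlabeled`` and ``views``.  Returns one row per combination
    with the six metrics at full precision (None where undefined).
    """
    if selections is None:
        selections = {"all": train.feature_names}
    rows = []
    for sel_name, feats in selections.items():
        feats = list(feats)
        for learner_name in learners:
            for method in methods:
                if method == "conventional":
                    model = make_learner(learner_name, seed=seed)
                    model.fit(train.labeled().X(feats), train.labeled().y01())
                    report = evaluate_learner(model, test, feats)
                    rows.append(_row(method, sel_name, learner_name, "-", report))
                elif method == "selftrain":
                    if unlabeled is None:
                        raise ValidationError("selftrain requires an unlabeled table")
                    model, _, _ = self_train(
                        learner_name, train, unlabeled,
                        selftrain_config or SelfTrainConfig(seed=seed), feats,
                    )
                    report = evaluate_learner(model, test, feats)
                    rows.append(_row(method, sel_name, learner_name, "-", report))
                elif method.startswith("cotrain"):
                    if unlabeled is None or views is None:
                        raise ValidationError("cotrain requires unlabeled data and views")
                    sub_views = ViewSpec(
                        tuple(f for f in views.view1 if f in feats),
                        tuple(f for f in views.view2 if f in feats),
                    )
                    h1, h2, _, _ = cotrain_multiview(
                        train, unlabeled, sub_views, learner_name, learner_name,
                        cotrain_config or CoTrainConfig(seed=seed),
                    )
                    rule = method.split("-", 1)[1] if "-" in method else "AND"
                    pred = combine_views(
                        h1.predict(test.X(sub_views.view1)),
                        h2.predict(test.X(sub_views.view2)),
                        rule,
                    )
                    report = metrics(confusion(pred, test.y01()))
                    rows.append(_row("cotrain", sel_name, learner_name, rule, report))
                else:
                    raise ValidationError(f"unknown method {method!r}")
    return pd.DataFrame(rows)


def _row(method: str, selection: str, learner: str, rule: str, report: MetricsReport) -> dict:
    out = {"method": method, "selection": selection, "learner": learner, "rule": rule}
    out.update(report.as_dict())
    return out


def report_to_csv(report: pd.DataFrame, path, decimals: int = 3) -> None:
    """Write a report at fixed decimals, undefined metrics as ``"undef"``."""
    out = report.copy()
    for col in METRIC_NAMES:
        if col in out.columns:
            out[col] = out[col].map(
                lambda v: UNDEF if v is None or (isinstance(v, float) and np.isnan(v))
                else f"{v:.{decimals}f}"
            )
    out.to_csv(path, index=False)


def report_to_json(report: pd.DataFrame, path) -> None:
    """Full-precision JSON dump of a report."""
    with open(path, "w") as fh:
        json.dump(report.to_dict(orient="records"), fh, indent=2, default=float)
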