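"""Base learners, self-training, and two-view co-training.

Two semi-supervised schemes are provided on top of a common base-learner
contract:

* **Self-training** (single view): a classifier fit on the labeled set L
  repeatedly pseudo-labels every unlabeled row whose maximum class
  probability strictly exceeds a threshold Θ (default 0.90) and absorbs it
  into L, until no row qualifies.

* **Two-view co-training** (Blum–Mitchell style): the feature space is
  partitioned into two views, each with its own classifier and its own
  unlabeled working pool of size u drawn from the unlabeled set U.  Each of
  k iterations fits both classifiers on the shared labeled set, harvests
  the p most confident positives and n most confident negatives from each
  pool, adds them to L as immutable pseudo-labels, and refills the pools
  from U.  Cross-teaching happens through the single shared L: rows labeled
  by one view's classifier are trained on by the other view's classifier at
  the next iteration.  An optional majority-class under-sampling step
  balances L once, before the first fit; harvested pseudo-labels then
  accumulate unrebalanced, so an n > p harvest progressively shifts the
  class ratio of the fit — the mechanism behind the specificity gains this
  scheme is used for.

Final per-view predictions are combined with the naive AND rule (positive
only if both views agree) or OR rule (positive if either view says so).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .core_data import NEGATIVE, POSITIVE, FeatureTable, ViewSpec
from .exceptions import ConfigurationError, ValidationError
from .preprocessing import undersample

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Base learners
# ---------------------------------------------------------------------------

class BaseLearner:
    """Uniform wrapper over the five supported classifiers.

    Exposes ``fit(X, y01)`` and ``predict_proba_positive(X)`` with the
    positive (severe-hypoglycemia) class coded 1.  Hyperparameters default
    to the library defaults; anything passed as ``params`` is forwarded to
    the underlying estimator.
    """

    def __init__(self, name: str, seed: int = 0, **params):
        self.name = name
        self.seed = seed
        self.params = params
        self._model = self._build()
        self.fitted = False

    def _build(self):
        seed, params = self.seed, self.params
        if self.name == "LR":
            return LogisticRegression(max_iter=1000, random_state=seed, **params)
        if self.name == "XGBoost":
            return XGBClassifier(random_state=seed, eval_metric="logloss", **params)
        if self.name == "NB":
            return GaussianNB(**params)
        if self.name == "SVM":
            return SVC(probability=True, random_state=seed, **params)
        if self.name == "RF":
            return RandomForestClassifier(random_state=seed, **params)
        raise ConfigurationError(
            f"unknown learner {self.name!r}; expected LR, XGBoost, NB, SVM or RF"
        )

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BaseLearner":
        if len(np.unique(y)) < 2:
            raise ValidationError(f"{self.name}: training set has a single class")
        self._model.fit(X, y)
        self.fitted = True
        return self

    def predict_proba_positive(self, X: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise ValidationError(f"{self.name}: predict before fit")
        classes = list(self._model.classes_)
        return self._model.predict_proba(X)[:, classes.index(1)]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        p1 = self.predict_proba_positive(X)
        return np.column_stack([1 - p1, p1])

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba_positive(X) >= threshold).astype(int)

    def clone(self, seed: int | None = None) -> "BaseLearner":
        return BaseLearner(self.name, seed if seed is not None else self.seed, **self.params)


def make_learner(name: str, seed: int = 0, **params) -> BaseLearner:
    return BaseLearner(name, seed=seed, **params)


def fit_base(
    learner: BaseLearner | str,
    train: FeatureTable,
    features: Sequence[str] | None = None,
    seed: int = 0,
) -> BaseLearner:
    """Fit a base learner on the labeled rows of a table, restricted to ``features``."""
    if isinstance(learner, str):
        learner = make_learner(learner, seed=seed)
    labeled = train.labeled()
    return learner.fit(labeled.X(features), labeled.y01())


# ---------------------------------------------------------------------------
# Self-training (single-view)
# ---------------------------------------------------------------------------

@dataclass
class SelfTrainConfig:
    theta: float = 0.90
    max_rounds: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.theta <= 1:
            raise ConfigurationError("theta must be in (0, 1]")
        if self.max_rounds < 1:
            raise ConfigurationError("max_rounds must be >= 1")


def self_train(
    learner: BaseLearner | str,
    L: FeatureTable,
    U: FeatureTable,
    config: SelfTrainConfig | None = None,
    features: Sequence[str] | None = None,
) -> tuple[BaseLearner, FeatureTable, pd.DataFrame]:
    """Iteratively absorb confident pseudo-labels from U into L.

    Each round fits the learner on the current L and moves every U row whose
    maximum class probability strictly exceeds Θ into L with its predicted
    label.  Stops when no row qualifies, U is empty, or ``max_rounds`` is
    reached.  The log records one row per pseudo-labeled example (round,
    subject id, label, confidence).
    """
    config = config or SelfTrainConfig()
    if isinstance(learner, str):
        learner = make_learner(learner, seed=config.seed)
    L = L.copy()
    U = U.copy()
    log_rows = []
    for round_no in range(1, config.max_rounds + 1):
        learner = learner.clone(config.seed)
        learner.fit(L.labeled().X(features), L.labeled().y01())
        if U.n_rows == 0:
            break
        p1 = learner.predict_proba_positive(U.X(features))
        conf = np.maximum(p1, 1 - p1)
        qualify = conf > config.theta
        if not qualify.any():
            break
        moved = U.index[qualify]
        labels = pd.Series(
            np.where(p1[qualify] >= 0.5, POSITIVE, NEGATIVE), index=moved
        )
        for sid, lab, c in zip(moved, labels, conf[qualify]):
            log_rows.append(
                {"round": round_no, "subject_id": sid, "label": lab, "confidence": float(c)}
            )
        L = L.concat(U.subset(moved).with_outcome(labels))
        U = U.subset(U.index[~qualify])
    log = pd.DataFrame(log_rows, columns=["round", "subject_id", "label", "confidence"])
    logger.info("self_train: %d pseudo-labels over %d rounds", len(log), round_no)
    return learner, L, log


# ---------------------------------------------------------------------------
# Confident-label harvesting
# ---------------------------------------------------------------------------

def harvest_confident(
    h: BaseLearner,
    pool: FeatureTable,
    p: int,
    n: int,
    features: Sequence[str] | None = None,
) -> tuple[FeatureTable, FeatureTable]:
    """Take the p most-confident positives and n most-confident negatives.

    Pool rows are ranked by predicted positive-class probability; the top p
    become positive pseudo-labels and the bottom n negative pseudo-labels
    (fewer if the pool is small; positives take precedence when p + n
    exceeds the pool).  Ties break to the earlier row in source order.
    Returns (pseudo-labeled rows, remaining pool).
    """
    if pool.n_rows == 0 or p + n == 0:
        return pool.subset([]).with_outcome(pd.Series(dtype=object)), pool
    prob = h.predict_proba_positive(pool.X(features))
    desc = np.argsort(-prob, kind="stable")  # stable: ties keep source order
    asc = np.argsort(prob, kind="stable")
    pos_rows = list(desc[: min(p, pool.n_rows)])
    neg_rows = [r for r in asc if r not in set(pos_rows)][:n]
    labels = pd.Series(
        [POSITIVE] * len(pos_rows) + [NEGATIVE] * len(neg_rows),
        index=pool.index[pos_rows + neg_rows],
    )
    harvested = pool.subset(labels.index).with_outcome(labels)
    taken = set(labels.index)
    remaining = pool.subset([i for i in pool.index if i not in taken])
    return harvested, remaining


# ---------------------------------------------------------------------------
# Two-view co-training
# ---------------------------------------------------------------------------

@dataclass
class CoTrainConfig:
    """Iteration count k, per-view harvest counts p/n, pool size u, seeds.

    ``undersample_ratio`` balances the initial labeled set to that
    majority-per-minority ratio once, before the first fit (``None``
    disables under-sampling).
    """

    k: int = 30
    p: int = 1
    n: int = 5
    u: int = 75
    undersample_ratio: float | None = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ConfigurationError("k must be >= 0")
        if self.p < 0 or self.n < 0 or self.p + self.n < 1:
            raise ConfigurationError("need p, n >= 0 and p + n >= 1")
        if self.u < self.p + self.n:
            raise ConfigurationError("pool size u must be >= p + n")
        if self.undersample_ratio is not None and self.undersample_ratio < 1:
            raise ConfigurationError("undersample_ratio must be >= 1 (or None)")

    @classmethod
    def preset(cls, ratio: str, **kwargs) -> "CoTrainConfig":
        """n:p harvest presets '3:1', '5:1', '7:1'."""
        n, p = (int(x) for x in ratio.split(":"))
        return cls(p=p, n=n, **kwargs)


@dataclass
class CoTrainState:
    L: FeatureTable
    U: FeatureTable
    pool1: FeatureTable
    pool2: FeatureTable
    h1: BaseLearner | None = None
    h2: BaseLearner | None = None
    log: list = field(default_factory=list)
    provenance: list = field(default_factory=list)  # per pseudo-label: view, iter, conf

    def row_count(self) -> int:
        return self.L.n_rows + self.U.n_rows + self.pool1.n_rows + self.pool2.n_rows


def _draw_pool(U: FeatureTable, u: int, rng: np.random.Generator) -> tuple[FeatureTable, FeatureTable]:
    take = min(u, U.n_rows)
    chosen = U.index[np.sort(rng.permutation(U.n_rows)[:take])]
    chosen_set = set(chosen)
    rest = U.subset([i for i in U.index if i not in chosen_set])
    return U.subset(chosen), rest


def cotrain_multiview(
    L: FeatureTable,
    U: FeatureTable,
    views: ViewSpec,
    learner1: BaseLearner | str,
    learner2: BaseLearner | str,
    config: CoTrainConfig | None = None,
    test: FeatureTable | None = None,
) -> tuple[BaseLearner, BaseLearner, FeatureTable, pd.DataFrame]:
    """Run Blum-style two-view co-training.

    The shared labeled set L is optionally under-sampled once, before the
    first iteration.  Per iteration: (a) fit h1 on view-1 columns and h2 on
    view-2 columns of the current L; (b) each classifier harvests its p
    most confident positives and n most confident negatives from its own
    pool; harvested rows join the shared L used by both learners at the
    next fit, which is the cross-teaching channel; (c) refill each pool
    from U up to u.  Pseudo-labels are never revised and never rebalanced.
    Stops early when both harvests are empty and U is exhausted.

    When a ``test`` table is given, per-iteration per-view confusion-matrix
    metrics on it are recorded in the returned iteration log.
    """
    from .evaluation import confusion, metrics  # local import to avoid a cycle

    config = config or CoTrainConfig()
    views.validate_against(L)
    if isinstance(learner1, str):
        learner1 = make_learner(learner1, seed=config.seed)
    if isinstance(learner2, str):
        learner2 = make_learner(learner2, seed=config.seed + 1)
    counts = L.class_counts()
    if counts[POSITIVE] == 0 or counts[NEGATIVE] == 0:
        raise ValidationError("co-training requires both classes in L")

    rng = np.random.default_rng(config.seed)
    L0 = L.copy()
    if config.undersample_ratio is not None:
        L0 = undersample(L0, config.undersample_ratio, seed=config.seed)
    pool1, U_rest = _draw_pool(U, config.u, rng)
    pool2, U_rest = _draw_pool(U_rest, config.u, rng)
    state = CoTrainState(L=L0, U=U_rest, pool1=pool1, pool2=pool2)
    initial_total = L0.n_rows + U.n_rows

    h1, h2 = learner1, learner2
    log_rows = []
    for it in range(1, config.k + 1):
        h1 = learner1.clone(config.seed + it)
        h2 = learner2.clone(config.seed + it + 1)
        h1.fit(state.L.labeled().X(views.view1), state.L.labeled().y01())
        h2.fit(state.L.labeled().X(views.view2), state.L.labeled().y01())

        got1, state.pool1 = harvest_confident(h1, state.pool1, config.p, config.n, views.view1)
        got2, state.pool2 = harvest_confident(h2, state.pool2, config.p, config.n, views.view2)
        for view_no, got, h, feats in ((1, got1, h1, views.view1), (2, got2, h2, views.view2)):
            if got.n_rows:
                conf = h.predict_proba_positive(got.X(feats))
                for sid, lab, c in zip(got.index, got.outcome, conf):
                    state.provenance.append(
                        {"subject_id": sid, "view": view_no, "iteration": it,
                         "label": lab, "positive_prob": float(c)}
                    )
                state.L = state.L.concat(got)

        state.pool1, state.U = _refill(state.pool1, state.U, config.u, rng)
        state.pool2, state.U = _refill(state.pool2, state.U, config.u, rng)

        row = {"iteration": it, "added_view1": got1.n_rows, "added_view2": got2.n_rows,
               "L_size": state.L.n_rows}
        if test is not None:
            y_test = test.y01()
            for view_no, h, feats in ((1, h1, views.view1), (2, h2, views.view2)):
                pred = h.predict(test.X(feats))
                m = metrics(confusion(pred, y_test))
                for name, value in m.as_dict().items():
                    row[f"view{view_no}_{name}"] = value
        log_rows.append(row)

        assert state.row_count() == initial_total, "row conservation violated"
        if got1.n_rows == 0 and got2.n_rows == 0 and state.U.n_rows == 0:
            break

    if config.k == 0 or not h1.fitted:
        # k = 0: fit once on (under-sampled) L with no harvesting
        h1 = learner1.clone(config.seed).fit(
            state.L.labeled().X(views.view1), state.L.labeled().y01()
        )
        h2 = learner2.clone(config.seed + 1).fit(
            state.L.labeled().X(views.view2), state.L.labeled().y01()
        )
    log = pd.DataFrame(log_rows)
    logger.info(
        "cotrain_multiview: %d iterations, |L| %d -> %d",
        len(log_rows), L.n_rows, state.L.n_rows,
    )
    return h1, h2, state.L, log


def _refill(
    pool: FeatureTable, U: FeatureTable, u: int, rng: np.random.Generator
) -> tuple[FeatureTable, FeatureTable]:
    need = u - pool.n_rows
    if need <= 0 or U.n_rows == 0:
        return pool, U
    drawn, rest = _draw_pool(U, need, rng)
    return pool.concat(drawn), rest


# ---------------------------------------------------------------------------
# View combination
# ---------------------------------------------------------------------------

def combine_views(pred1: Sequence[int], pred2: Sequence[int], rule: str = "AND") -> np.ndarray:
    """Combine hard per-view labels with the naive AND or OR rule."""
    a = np.asarray(pred1, dtype=int)
    b = np.asarray(pred2, dtype=int)
    if a.shape != b.shape:
        raise ValidationError(f"prediction length mismatch: {a.shape} vs {b.shape}")
    rule = rule.upper()
    if rule == "AND":
        return (a & b).astype(int)
    if rule == "OR":
        return (a | b).astype(int)
    raise ConfigurationError(f"unknown combination rule {rule!r}")
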