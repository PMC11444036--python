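"""Automatic feature selection: LASSO, Boruta, MRMR, and consensus voting.

Three automatic selectors complement the expert ("MD") feature list:

* **LASSO** — L1-penalized logistic regression over a regularization path;
  the penalty is chosen by cross-validated deviance with the
  one-standard-error rule, and features with nonzero coefficients at the
  chosen penalty are selected.
* **Boruta** — all-relevant selection: each candidate competes against
  permuted "shadow" copies of the features under a random-forest importance
  measure, with confirmation/rejection by a Bonferroni-corrected two-sided
  binomial test on the accumulated hit counts.
* **MRMR** — greedy forward selection maximizing mutual-information
  relevance to the label minus mean redundancy with already-selected
  features (the difference criterion); continuous features are discretized
  by quartile binning.

A consensus rule intersects the selected sets ("selected by all"), and a
majority rule keeps features chosen by more than half of the base methods.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import binom
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss, mutual_info_score, roc_auc_score

from .core_data import FeatureTable, kfold_indices
from .exceptions import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class SelectionResult:
    """Outcome of one selector: ordered selected names plus per-feature scores."""

    method: str
    selected: list[str]
    scores: dict[str, float] = field(default_factory=dict)


@dataclass
class ConsensusResult:
    base: list[SelectionResult]
    rule: str
    effective: list[str]


# ---------------------------------------------------------------------------
# LASSO
# ---------------------------------------------------------------------------

def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    return (X[:, keep] - mu[keep]) / sd[keep], keep


def lasso_select(
    table: FeatureTable,
    seed: int = 0,
    folds: int = 5,
    n_penalties: int = 50,
) -> SelectionResult:
    """L1-penalized logistic selection with the one-standard-error rule.

    Features are standardized internally; the regularization path spans
    ``n_penalties`` log-spaced values of C.  The chosen penalty is the
    strongest whose cross-validated mean deviance lies within one standard
    error of the minimum.  Constant features are excluded with a warning.
    """
    labeled = table.labeled()
    y = labeled.y01()
    if len(np.unique(y)) < 2:
        raise ValidationError("lasso_select requires both classes")
    X = labeled.X()
    Xs, keep = _standardize(X)
    names = [n for n, k in zip(labeled.feature_names, keep) if k]
    dropped = [n for n, k in zip(labeled.feature_names, keep) if not k]
    if dropped:
        warnings.warn(f"constant features excluded from LASSO: {dropped}")

    Cs = np.logspace(-3, 2, n_penalties)
    fold_sets = kfold_indices(labeled, folds=folds, seed=seed)
    all_rows = np.arange(len(y))
    dev = np.full((folds, len(Cs)), np.nan)
    for f, test_rows in enumerate(fold_sets):
        train_rows = np.setdiff1d(all_rows, test_rows)
        if len(np.unique(y[train_rows])) < 2 or len(np.unique(y[test_rows])) < 2:
            continue
        for j, C in enumerate(Cs):
            model = LogisticRegression(
                l1_ratio=1.0, C=C, solver="liblinear", random_state=seed, max_iter=2000
            )
            model.fit(Xs[train_rows], y[train_rows])
            prob = model.predict_proba(Xs[test_rows])[:, 1]
            dev[f, j] = 2 * log_loss(y[test_rows], prob, labels=[0, 1])
    mean_dev = np.nanmean(dev, axis=0)
    n_ok = np.sum(~np.isnan(dev), axis=0)
    se_dev = np.nanstd(dev, axis=0, ddof=1) / np.sqrt(np.maximum(n_ok, 1))
    best = int(np.nanargmin(mean_dev))
    threshold = mean_dev[best] + se_dev[best]
    # smallest C (strongest penalty) within one SE of the minimum
    chosen = next(j for j in range(len(Cs)) if mean_dev[j] <= threshold)
    final = LogisticRegression(
        l1_ratio=1.0, C=Cs[chosen], solver="liblinear", random_state=seed, max_iter=2000
    )
    final.fit(Xs, y)
    coef = final.coef_.ravel()
    scores = {n: 0.0 for n in labeled.feature_names}
    scores.update({n: abs(c) for n, c in zip(names, coef)})
    selected = [n for n in labeled.feature_names if scores[n] > 0]
    logger.info("lasso_select: C=%.4g, %d/%d selected", Cs[chosen], len(selected), len(names))
    return SelectionResult("LASSO", selected, scores)


# ---------------------------------------------------------------------------
# Boruta
# ---------------------------------------------------------------------------

def boruta_select(
    table: FeatureTable,
    max_iter: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    n_estimators: int = 100,
) -> SelectionResult:
    """All-relevant selection against shadow features.

    Each iteration appends a permuted copy of every candidate column, fits a
    random forest on the extended matrix, and scores a "hit" for every real
    feature whose impurity importance exceeds the maximum shadow importance.
    Accumulated hits are tested against Binomial(t, 1/2) two-sided with a
    Bonferroni correction over the candidates; features confirmed at level
    ``alpha`` are selected, rejected ones drop out of further testing, and
    features still tentative after ``max_iter`` iterations are not selected.
    The reported score is the z-statistic of the final hit count.
    """
    if max_iter < 1:
        raise ConfigurationError("max_iter must be >= 1")
    labeled = table.labeled()
    if labeled.n_rows == 0:
        raise ValidationError("boruta_select requires labeled rows")
    y = labeled.y01()
    X = labeled.X()
    n_feat = X.shape[1]
    names = labeled.feature_names
    rng = np.random.default_rng(seed)

    hits = np.zeros(n_feat, dtype=int)
    trials = np.zeros(n_feat, dtype=int)
    status = np.zeros(n_feat, dtype=int)  # 0 tentative, +1 confirmed, -1 rejected
    bonferroni = max(n_feat, 1)
    for t in range(1, max_iter + 1):
        active = status == 0
        if not active.any():
            break
        shadow = np.column_stack([rng.permutation(X[:, j]) for j in range(n_feat)])
        forest = RandomForestClassifier(
            n_estimators=n_estimators, random_state=int(rng.integers(2**31))
        )
        forest.fit(np.hstack([X, shadow]), y)
        importances = forest.feature_importances_
        shadow_max = importances[n_feat:].max()
        hits[active] += importances[:n_feat][active] > shadow_max
        trials[active] += 1
        for j in np.nonzero(active)[0]:
            p_hi = binom.sf(hits[j] - 1, trials[j], 0.5)
            p_lo = binom.cdf(hits[j], trials[j], 0.5)
            if p_hi < alpha / (2 * bonferroni):
                status[j] = 1
            elif p_lo < alpha / (2 * bonferroni):
                status[j] = -1
    with np.errstate(invalid="ignore"):
        z = (hits - trials / 2) / np.sqrt(np.maximum(trials, 1) / 4)
    scores = {n: float(z[j]) for j, n in enumerate(names)}
    selected = [n for j, n in enumerate(names) if status[j] == 1]
    logger.info(
        "boruta_select: %d confirmed, %d rejected, %d tentative after %d iterations",
        int((status == 1).sum()), int((status == -1).sum()), int((status == 0).sum()), t,
    )
    return SelectionResult("Boruta", selected, scores)


# ---------------------------------------------------------------------------
# MRMR
# ---------------------------------------------------------------------------

def _discretize(x: np.ndarray, bins: int = 4) -> np.ndarray:
    """Quartile-bin a continuous column; binary columns pass through."""
    uniq = np.unique(x)
    if len(uniq) <= bins:
        return np.searchsorted(uniq, x)
    edges = np.unique(np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1]))
    return np.digitize(x, edges)


def mutual_information(x: np.ndarray, y: np.ndarray, bins: int = 4) -> float:
    """Mutual information (nats) between a feature and a discrete target."""
    return float(mutual_info_score(_discretize(x, bins), y))


def mrmr_select(table: FeatureTable, k: int, bins: int = 4) -> SelectionResult:
    """Greedy minimum-redundancy maximum-relevance selection.

    Relevance is the mutual information between a (quartile-binned) feature
    and the label; redundancy is the mean mutual information between the
    candidate and the already-selected features.  The difference criterion
    (relevance − redundancy) is maximized at each step; ties resolve to the
    earliest feature in source-column order.  Deterministic.
    """
    labeled = table.labeled()
    names = labeled.feature_names
    if not 1 <= k <= len(names):
        raise ConfigurationError(f"k={k} out of range 1..{len(names)}")
    y = labeled.y01()
    disc = {n: _discretize(labeled.data[n].to_numpy(dtype=float), bins) for n in names}
    relevance = {n: float(mutual_info_score(disc[n], y)) for n in names}

    selected: list[str] = []
    scores: dict[str, float] = {}
    remaining = list(names)
    while len(selected) < k:
        best_name, best_crit = None, -np.inf
        for n in remaining:
            if selected:
                redundancy = float(
                    np.mean([mutual_info_score(disc[n], disc[s]) for s in selected])
                )
            else:
                redundancy = 0.0
            crit = relevance[n] - redundancy
            if crit > best_crit:
                best_name, best_crit = n, crit
        selected.append(best_name)
        scores[best_name] = best_crit
        remaining.remove(best_name)
    for n in remaining:
        redundancy = float(np.mean([mutual_info_score(disc[n], disc[s]) for s in selected]))
        scores[n] = relevance[n] - redundancy
    return SelectionResult("MRMR", selected, scores)


def mrmr_k_sweep(
    table: FeatureTable,
    k_max: int,
    learner: str = "RF",
    folds: int = 5,
    seed: int = 0,
) -> tuple[int, np.ndarray]:
    """Sweep the MRMR feature count and score each k by cross-validated AUROC.

    For k = 1..k_max the top-k MRMR features are evaluated with the named
    base learner under stratified k-fold cross-validation; returns the
    smallest k attaining the maximal mean AUROC together with the AUC curve.
    """
    from .cotraining import make_learner  # local import to avoid a cycle

    labeled = table.labeled()
    if k_max > len(labeled.feature_names):
        raise ConfigurationError("k_max exceeds feature count")
    full = mrmr_select(labeled, k_max)
    y = labeled.y01()
    fold_sets = kfold_indices(labeled, folds=folds, seed=seed)
    all_rows = np.arange(len(y))
    aucs = np.empty(k_max)
    for k in range(1, k_max + 1):
        X = labeled.X(full.selected[:k])
        fold_aucs = []
        for f, test_rows in enumerate(fold_sets):
            train_rows = np.setdiff1d(all_rows, test_rows)
            if len(np.unique(y[test_rows])) < 2:
                continue
            model = make_learner(learner, seed=seed + f)
            model.fit(X[train_rows], y[train_rows])
            fold_aucs.append(roc_auc_score(y[test_rows], model.predict_proba_positive(X[test_rows])))
        aucs[k - 1] = float(np.mean(fold_aucs))
    best_k = int(np.argmax(aucs)) + 1  # argmax returns the first (smallest) maximizer
    logger.info("mrmr_k_sweep: best_k=%d, AUC=%.3f", best_k, aucs[best_k - 1])
    return best_k, aucs


# ---------------------------------------------------------------------------
# Consensus / majority vote
# ---------------------------------------------------------------------------

def consensus_vote(
    results: Sequence[SelectionResult],
    rule: str = "consensus",
    candidate_order: Sequence[str] | None = None,
) -> ConsensusResult:
    """Combine base selections by intersection or majority.

    ``consensus`` keeps features selected by every base method; ``majority``
    keeps features selected by more than half of them.  Output order follows
    ``candidate_order`` (default: order of first appearance across the base
    results).
    """
    if len(results) < 2:
        raise ConfigurationError("consensus requires at least two base results")
    if rule not in ("consensus", "majority"):
        raise ConfigurationError(f"unknown rule {rule!r}")
    if candidate_order is None:
        candidate_order = []
        for r in results:
            for n in r.selected:
                if n not in candidate_order:
                    candidate_order.append(n)
    sets = [set(r.selected) for r in results]
    if rule == "consensus":
        keep = set.intersection(*sets)
    else:
        keep = {n for n in candidate_order if sum(n in s for s in sets) > len(sets) / 2}
    effective = [n for n in candidate_order if n in keep]
    if not effective:
        warnings.warn(f"{rule} vote produced an empty selection")
    return ConsensusResult(list(results), rule, effective)
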