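import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from sklearn.metrics import mutual_info_score

from mvcotrain import (
    boruta_select,
    consensus_vote,
    lasso_select,
    mrmr_k_sweep,
    mrmr_select,
)
from mvcotrain.feature_selection import SelectionResult, _discretize
from mvcotrain.exceptions import ConfigurationError
from tests.conftest import make_table


def informative_plus_noise(n=500, n_noise=9, slope=2.0, seed=1):
    """One near-copy of the label's generating score among pure noise."""
    rng = np.random.default_rng(seed)
    score = rng.standard_normal(n)
    y = (rng.random(n) < expit(slope * score)).astype(int)
    X = np.column_stack(
        [score + 0.01 * rng.standard_normal(n)]
        + [rng.standard_normal(n) for _ in range(n_noise)]
    )
    names = ["inf"] + [f"noise{j}" for j in range(n_noise)]
    return make_table(X, y, names)


class TestLasso:
    def test_informative_kept_noise_dropped(self):
        table = informative_plus_noise()
        result = lasso_select(table, seed=1)
        assert "inf" in result.selected
        noise_kept = [f for f in result.selected if f.startswith("noise")]
        assert len(noise_kept) <= 1

    def test_duplicated_informative_feature_selection_nonempty(self):
        table = informative_plus_noise(n=400, n_noise=3)
        dup = table.data.copy()
        dup["inf_copy"] = dup["inf"]
        table = make_table(dup.to_numpy(), table.y01(), list(dup.columns))
        result = lasso_select(table, seed=1)
        assert result.selected
        assert set(result.selected) <= {"inf", "inf_copy", "noise0", "noise1", "noise2"}
        assert {"inf", "inf_copy"} & set(result.selected)

    def test_scores_cover_all_candidates(self):
        table = informative_plus_noise(n=200, n_noise=3)
        result = lasso_select(table, seed=0)
        assert set(result.scores) == set(table.feature_names)


class TestBoruta:
    def test_pure_noise_confirms_nothing(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((200, 10))
        y = rng.integers(0, 2, 200)
        table = make_table(X, y)
        result = boruta_select(table, max_iter=100, alpha=0.05, seed=1)
        assert result.selected == []

    def test_separating_feature_confirmed(self):
        rng = np.random.default_rng(1)
        n = 200
        y = np.repeat([0, 1], n // 2)
        X = np.column_stack([3.0 * y + 0.1 * rng.standard_normal(n)]
                            + [rng.standard_normal(n) for _ in range(5)])
        table = make_table(X, y, ["sep"] + [f"n{j}" for j in range(5)])
        result = boruta_select(table, max_iter=100, alpha=0.05, seed=1)
        assert "sep" in result.selected

    def test_single_iteration_leaves_everything_tentative(self):
        rng = np.random.default_rng(0)
        table = make_table(rng.standard_normal((50, 4)), rng.integers(0, 2, 50))
        result = boruta_select(table, max_iter=1, seed=0)
        assert result.selected == []

    def test_type_one_error_controlled_on_permuted_labels(self):
        # family-wise confirmation rate on label-permuted data stays below
        # 2*alpha across seeded replicates
        alpha = 0.05
        replicates = 200
        rng = np.random.default_rng(42)
        X = rng.standard_normal((60, 5))
        false_alarms = 0
        for rep in range(replicates):
            y = np.random.default_rng(rep).permutation(np.repeat([0, 1], 30))
            table = make_table(X, y)
            result = boruta_select(
                table, max_iter=12, alpha=alpha, seed=rep, n_estimators=25
            )
            false_alarms += bool(result.selected)
        assert false_alarms / replicates <= 2 * alpha


def brute_force_mrmr(table, k, bins=4):
    """Independent greedy-criterion evaluation by exhaustive candidate scan."""
    y = table.y01()
    disc = {n: _discretize(table.data[n].to_numpy(float), bins) for n in table.feature_names}
    chosen = []
    for _ in range(k):
        scored = []
        for n in table.feature_names:
            if n in chosen:
                continue
            rel = mutual_info_score(disc[n], y)
            red = np.mean([mutual_info_score(disc[n], disc[s]) for s in chosen]) if chosen else 0.0
            scored.append((rel - red, n))
        best = max(scored, key=lambda t: t[0])
        # stable tie-break: earliest candidate attaining the max
        best_val = best[0]
        for val, n in scored:
            if val == best_val:
                chosen.append(n)
                break
    return chosen


class TestMrmr:
    def test_redundant_copy_skipped(self):
        rng = np.random.default_rng(3)
        n = 600
        x1 = rng.standard_normal(n)
        y = (x1 + 0.5 * rng.standard_normal(n) > 0).astype(int)
        x3 = np.where(y == 1, 0.4, -0.4) + rng.standard_normal(n)
        table = make_table(np.column_stack([x1, x1.copy(), x3]), y, ["X1", "X2", "X3"])
        assert mrmr_select(table, 2).selected == ["X1", "X3"]

    def test_k_equals_feature_count_selects_all(self):
        rng = np.random.default_rng(4)
        table = make_table(rng.standard_normal((80, 4)), rng.integers(0, 2, 80))
        result = mrmr_select(table, 4)
        assert sorted(result.selected) == sorted(table.feature_names)

    def test_single_candidate(self):
        rng = np.random.default_rng(5)
        table = make_table(rng.standard_normal((30, 1)), np.repeat([0, 1], 15))
        assert mrmr_select(table, 1).selected == ["f0"]

    def test_first_pick_is_max_relevance(self):
        rng = np.random.default_rng(6)
        n = 400
        y = np.repeat([0, 1], n // 2)
        X = np.column_stack([rng.standard_normal(n), 1.5 * y + rng.standard_normal(n),
                             0.3 * y + rng.standard_normal(n)])
        table = make_table(X, y)
        y01 = table.y01()
        relevances = [
            mutual_info_score(_discretize(table.data[n_].to_numpy(float)), y01)
            for n_ in table.feature_names
        ]
        assert mrmr_select(table, 1).selected[0] == table.feature_names[int(np.argmax(relevances))]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_brute_force_on_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        n_feat = rng.integers(3, 7)
        n = 120
        y = rng.integers(0, 2, n)
        X = rng.standard_normal((n, n_feat)) + 0.6 * y[:, None] * rng.random(n_feat)
        table = make_table(X, y)
        for k in range(1, n_feat + 1):
            assert mrmr_select(table, k).selected == brute_force_mrmr(table, k)

    def test_k_out_of_range(self):
        rng = np.random.default_rng(0)
        table = make_table(rng.standard_normal((30, 3)), np.repeat([0, 1], 15))
        with pytest.raises(ConfigurationError):
            mrmr_select(table, 0)
        with pytest.raises(ConfigurationError):
            mrmr_select(table, 4)


def planted_table(n_informative, n=800, delta=0.8, n_total=10, seed=1):
    rng = np.random.default_rng(seed)
    y = np.zeros(n, dtype=int)
    y[: n // 3] = 1
    y = y[rng.permutation(n)]
    cols = [delta * y + rng.standard_normal(n) for _ in range(n_informative)]
    cols += [rng.standard_normal(n) for _ in range(n_total - n_informative)]
    names = [f"inf{j}" for j in range(n_informative)] + [
        f"noise{j}" for j in range(n_total - n_informative)
    ]
    return make_table(np.column_stack(cols), y, names)


class TestKSweep:
    def test_auc_vector_length_is_k_max(self):
        table = planted_table(1, n=200, n_total=4)
        _, aucs = mrmr_k_sweep(table, 4, "NB", seed=1)
        assert len(aucs) == 4

    def test_best_k_matches_planted_informative_count(self):
        assert mrmr_k_sweep(planted_table(1), 6, "NB", seed=1)[0] == 1
        assert mrmr_k_sweep(planted_table(2), 6, "NB", seed=1)[0] == 2


class TestConsensus:
    def r(self, name, selected):
        return SelectionResult(name, list(selected))

    def test_intersection(self):
        result = consensus_vote(
            [self.r("a", "AB"), self.r("b", "AC"), self.r("c", "A")], "consensus"
        )
        assert result.effective == ["A"]

    def test_majority_is_superset_of_consensus(self):
        base = [self.r("a", "ABX"), self.r("b", "AB"), self.r("c", "AC")]
        cons = consensus_vote(base, "consensus").effective
        majority = consensus_vote(base, "majority").effective
        assert set(cons) <= set(majority)
        assert majority == ["A", "B"]

    def test_reported_cohort_selections_intersect_to_four(self):
        # the three automatic selectors' published picks over the 17
        # expert variables agree on exactly four features
        lasso = self.r("LASSO", ["HbA1c", "FPG", "g1check", "g1diabed", "g1nutrit",
                                 "Sulfonylureas", "NPH/L insulin", "Othbol insulin",
                                 "Premixed insulin"])
        boruta = self.r("Boruta", ["HbA1c", "FPG", "g1check", "g1diabed", "g1nutrit",
                                   "NPH/L insulin", "Othbol insulin"])
        mrmr = self.r("MRMR", ["HbA1c", "FPG", "g1diabed", "NPH/L insulin"])
        result = consensus_vote([lasso, boruta, mrmr], "consensus")
        assert result.effective == ["HbA1c", "FPG", "g1diabed", "NPH/L insulin"]

    def test_disjoint_sets_give_empty_consensus(self):
        with pytest.warns(UserWarning, match="empty"):
            result = consensus_vote([self.r("a", "A"), self.r("b", "B")], "consensus")
        assert result.effective == []

    def test_requires_two_results(self):
        with pytest.raises(ConfigurationError):
            consensus_vote([self.r("a", "A")], "consensus")
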