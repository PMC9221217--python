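"""Mutual information, MRMR ranking and the SFC window search.

The MRMR trace is checked against an independent per-step recomputation of
the greedy objective (with its own MI implementation), and sfc_search against
an independently coded exhaustive window enumerator.
"""

import math
from collections import Counter

import numpy as np
import pytest

from atlasfusion import (
    FeatureTable,
    mrmr_rank,
    mutual_information,
    quantile_bins,
    sfc_search,
)


# --- independent oracles (deliberately different implementations) -----------


def mi_oracle(a, b):
    """Plug-in MI in bits via Counter arithmetic (oracle for the package MI)."""
    n = len(a)
    pa = Counter(a)
    pb = Counter(b)
    pab = Counter(zip(a, b))
    total = 0.0
    for (va, vb), c in pab.items():
        pxy = c / n
        total += pxy * math.log2(pxy / ((pa[va] / n) * (pb[vb] / n)))
    return total


def exhaustive_window_oracle(length, evaluator, ranked):
    """Enumerate all contiguous windows; best by (score, -size, -start)."""
    candidates = []
    for s in range(1, length):
        for e in range(s + 1, length + 1):
            candidates.append((evaluator(ranked[s - 1 : e]), -(e - s), -s, (s, e)))
    return max(candidates)[3]


# --- mutual information ------------------------------------------------------


def test_mi_matches_hand_computed_2x2_table():
    # joint counts 40/10/10/40 over n=100
    x = np.concatenate([np.zeros(40), np.ones(10), np.zeros(10), np.ones(40)])
    y = np.concatenate([np.zeros(50, int), np.ones(50, int)])
    expected = (
        2 * 0.4 * math.log2(0.4 / 0.25) + 2 * 0.1 * math.log2(0.1 / 0.25)
    )
    assert mutual_information(x, y, n_bins=2) == pytest.approx(expected, abs=1e-12)


def test_mi_of_deterministic_threshold_is_label_entropy():
    x = np.arange(100, dtype=float)
    y = (x >= 50).astype(int)
    assert mutual_information(x, y, n_bins=2) == pytest.approx(1.0, abs=1e-12)


def test_mi_near_zero_for_scrambled_labels():
    rng = np.random.default_rng(0)
    x = rng.standard_normal(200)
    y = np.tile([0, 1], 100)
    y = y[rng.permutation(200)]
    assert mutual_information(x, y, n_bins=5) <= 0.1


def test_mi_symmetric_under_label_relabeling(rng):
    x = rng.standard_normal(120)
    y = rng.integers(0, 2, 120)
    assert mutual_information(x, y) == pytest.approx(mutual_information(x, 1 - y), abs=1e-12)


def test_constant_feature_has_zero_mi():
    y = np.tile([0, 1], 50)
    assert mutual_information(np.ones(100), y) == 0.0


def test_quantile_bins_splits_ties_by_rank():
    x = np.zeros(10)  # all tied
    bins = quantile_bins(x, 2)
    assert sorted(bins.tolist()) == [0] * 5 + [1] * 5


# --- MRMR --------------------------------------------------------------------


def _table(values, labels):
    return FeatureTable(values=np.asarray(values, float), labels=np.asarray(labels))


def test_duplicate_of_top_feature_is_demoted_below_weak_independent():
    rng = np.random.default_rng(1)
    n = 60
    y = np.tile([0, 1], n // 2)
    f1 = y + 0.2 * rng.standard_normal(n)  # strongly relevant
    f2 = f1.copy()  # exact duplicate: fully redundant
    f3 = y + 1.5 * rng.standard_normal(n)  # weaker but independent
    ranked = mrmr_rank(_table(np.column_stack([f1, f2, f3]), y), k=3)
    assert ranked == [0, 2, 1]


def test_perfect_separator_ranks_first(rng):
    n = 40
    y = np.tile([0, 1], n // 2)
    noise = rng.standard_normal((n, 5))
    values = np.column_stack([noise[:, :3], y.astype(float), noise[:, 3:]])
    assert mrmr_rank(_table(values, y), k=4)[0] == 3


@pytest.mark.parametrize("n_features", [8, 12])
def test_greedy_trace_matches_objective_recomputation(n_features, rng):
    n = 50
    y = np.tile([0, 1], n // 2)
    values = rng.standard_normal((n, n_features))
    values[:, 0] += y
    values[:, 1] += 0.5 * y
    values[:, 2] = values[:, 0] + 0.1 * rng.standard_normal(n)
    table = _table(values, y)
    k = n_features - 2
    got = mrmr_rank(table, k=k, n_bins=5)
    binned = [tuple(quantile_bins(values[:, j], 5)) for j in range(n_features)]
    relevance = [mi_oracle(binned[j], tuple(y)) for j in range(n_features)]
    # step-wise optimality of the greedy trace against an independent
    # objective recomputation (float near-ties are legal either way)
    assert relevance[got[0]] >= max(relevance) - 1e-9
    for step in range(1, k):
        chosen = got[:step]
        rest = [j for j in range(n_features) if j not in chosen]
        scores = {
            j: relevance[j]
            - sum(mi_oracle(binned[j], binned[s]) for s in chosen) / step
            for j in rest
        }
        assert scores[got[step]] >= max(scores.values()) - 1e-9


def test_ranking_invariant_to_column_permutation(rng):
    n = 50
    y = np.tile([0, 1], n // 2)
    values = rng.standard_normal((n, 6))
    values[:, 0] += 2 * y
    values[:, 4] += y
    perm = [3, 0, 5, 1, 4, 2]
    ranked = mrmr_rank(_table(values, y), k=6)
    ranked_perm = mrmr_rank(_table(values[:, perm], y), k=6)
    assert [perm[j] for j in ranked_perm] == ranked


def test_k_below_two_rejected(rng):
    y = np.tile([0, 1], 10)
    with pytest.raises(ValueError):
        mrmr_rank(_table(rng.standard_normal((20, 4)), y), k=1)


# --- SFC ---------------------------------------------------------------------


def test_window_around_a_pivotal_feature():
    ranked = [11, 5, 9, 7, 2, 4]  # feature id 7 sits at 0-based position 3

    def evaluator(subset):
        return 1.0 if 7 in subset else 0.6

    result = sfc_search(ranked, evaluator)
    assert result.window == (3, 4)
    assert result.window_score == 1.0
    assert result.window == exhaustive_window_oracle(6, evaluator, ranked)


def test_constant_evaluator_tie_breaks_to_smallest_window():
    result = sfc_search(list(range(6)), lambda s: 0.5)
    assert result.window == (1, 2)


def test_evaluation_count_is_l_choose_2():
    calls = []

    def evaluator(subset):
        calls.append(tuple(subset))
        return 0.5

    result = sfc_search(list(range(50)), evaluator)
    assert result.n_evaluations == 1225
    assert len(calls) == 1225
    assert len(set(calls)) == 1225  # every window evaluated exactly once


@pytest.mark.parametrize("seed", range(5))
def test_matches_independent_enumerator_on_random_evaluators(seed):
    rng = np.random.default_rng(seed)
    length = int(rng.integers(4, 12))
    ranked = rng.permutation(100)[:length].tolist()
    table = {}

    def evaluator(subset):
        key = tuple(subset)
        if key not in table:
            table[key] = float(rng.integers(0, 4)) / 4.0
        return table[key]

    # pre-populate deterministically so both searches see identical scores
    for s in range(1, length):
        for e in range(s + 1, length + 1):
            evaluator(ranked[s - 1 : e])
    result = sfc_search(ranked, evaluator)
    assert result.window == exhaustive_window_oracle(length, evaluator, ranked)
    assert result.window_score == pytest.approx(evaluator(result.selected_ids))


def test_window_score_reproducible_from_selected_features():
    ranked = [3, 1, 4, 5, 9, 2]

    def evaluator(subset):
        return len(subset) / 10.0 if 9 in subset else 0.0

    result = sfc_search(ranked, evaluator)
    assert evaluator(result.selected_ids) == pytest.approx(result.window_score)


def test_single_feature_ranking_rejected():
    with pytest.raises(ValueError):
        sfc_search([1], lambda s: 1.0)


# --- FeatureTable hygiene ----------------------------------------------------


def test_missing_value_features_are_dropped_with_warning(caplog):
    values = np.random.default_rng(0).standard_normal((10, 3))
    values[4, 1] = np.nan
    table = FeatureTable(values=values, labels=np.tile([0, 1], 5), feature_names=["a", "b", "c"])
    assert table.feature_names == ["a", "c"]
    assert table.n_features == 2
    assert any("missing" in r.getMessage() for r in caplog.records)


def test_single_class_table_rejected():
    with pytest.raises(ValueError):
        FeatureTable(values=np.zeros((4, 2)), labels=np.ones(4))


def test_csv_round_trip(tmp_path, rng):
    table = FeatureTable(
        values=rng.standard_normal((6, 2)),
        labels=np.tile([0, 1], 3),
        feature_names=["aal:HE:hippocampus", "aal:GMV:amygdala"],
    )
    path = tmp_path / "t.csv"
    table.to_csv(path)
    back = FeatureTable.from_csv(path)
    assert np.allclose(back.values, table.values)
    assert back.feature_meta[0] == ("aal", "HE", "hippocampus")
    assert np.array_equal(back.labels, table.labels)
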