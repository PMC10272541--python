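import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from shgquant import (
    FIBROSIS_DICHOTOMIES,
    dichotomize,
    evaluate_table,
    roc_auc,
    spearman,
)


def brute_force_auc(index, labels):
    """All-pairs concordance count (the oracle)."""
    index = np.asarray(index, float)
    labels = np.asarray(labels)
    pos = index[labels == 1]
    neg = index[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        return float("nan")
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_spearman_monotone_and_antitone():
    assert spearman([1, 2, 3], [3, 5, 9])[0] == pytest.approx(1.0)
    assert spearman([1, 2, 3], [9, 5, 3])[0] == pytest.approx(-1.0)


def test_spearman_midranks_match_hand_computation():
    # x=[1,2,2,3] -> midranks [1, 2.5, 2.5, 4]; y=[1,3,2,4] -> [1,3,2,4]
    # Pearson of those ranks = 4.5 / sqrt(4.5 * 5)
    r, _ = spearman([1, 2, 2, 3], [1, 3, 2, 4])
    assert r == pytest.approx(4.5 / np.sqrt(4.5 * 5.0))


def test_spearman_constant_vector_is_an_error():
    with pytest.raises(ValueError):
        spearman([1, 1, 1], [1, 2, 3])
    with pytest.raises(ValueError):
        spearman([1, 2], [1, 2])


def test_dichotomize_named_splits():
    assert dichotomize([0, 1, 2, 3, 4], "01vs.234").tolist() == [0, 0, 1, 1, 1]
    assert dichotomize([0, 3], "0vs.123").tolist() == [0, 1]
    with pytest.raises(ValueError):
        dichotomize([0, 1], "0-1")
    with pytest.raises(ValueError):
        dichotomize([0, 5], "01vs.234")


def test_roc_auc_worked_example_and_edge_cases():
    assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)
    assert roc_auc([1, 2, 3, 10], [0, 0, 1, 1]) == 1.0
    assert roc_auc([5, 5, 5, 5], [0, 0, 1, 1]) == pytest.approx(0.5)
    assert np.isnan(roc_auc([1, 2, 3], [1, 1, 1]))  # single class -> NA


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_roc_auc_matches_brute_force_concordance(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 50))
    scores = np.round(rng.normal(size=n), 1)  # coarse values force ties
    labels = rng.integers(0, 2, size=n)
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    assert roc_auc(scores, labels) == pytest.approx(brute_force_auc(scores, labels))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_auc_invariant_under_monotone_transform_and_flip(seed):
    rng = np.random.default_rng(seed)
    scores = rng.normal(size=30)
    labels = rng.integers(0, 2, size=30)
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    auc = roc_auc(scores, labels)
    assert roc_auc(np.exp(scores), labels) == pytest.approx(auc)
    assert roc_auc(3 * scores + 7, labels) == pytest.approx(auc)
    # tie-free scores: flipping the index mirrors the AUC
    assert roc_auc(-scores, labels) == pytest.approx(1 - auc)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_spearman_invariant_under_strictly_monotone_transform(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=25)
    y = rng.normal(size=25)
    r0 = spearman(x, y)[0]
    assert spearman(np.exp(x), y)[0] == pytest.approx(r0)
    assert spearman(x, y**3 + 5 * y)[0] == pytest.approx(r0)


def test_evaluate_table_perfect_index_and_na_cells():
    table = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(10)],
            "stage": [0, 0, 1, 1, 2, 2, 3, 3, 4, 4],
            "perfect": [0, 0, 1, 1, 2, 2, 3, 3, 4, 4.0],
        }
    )
    report = evaluate_table(table, ["perfect"], "stage")
    for split in FIBROSIS_DICHOTOMIES:
        assert report.table.loc[split, "perfect"] == 1.0
    assert report.table.loc["Spearman_R", "perfect"] == pytest.approx(1.0)
    # cohort covering only stages 2-4: dichotomy 0vs.1234 has an empty side
    sub = table[table["stage"] >= 2]
    rep = evaluate_table(sub, ["perfect"], "stage")
    assert np.isnan(rep.table.loc["0vs.1234", "perfect"])
    assert np.isnan(rep.table.loc["01vs.234", "perfect"])  # both 0 and 1 missing
    assert rep.table.loc["012vs.34", "perfect"] == 1.0


def test_evaluate_table_noise_column_near_chance():
    rng = np.random.default_rng(123)
    table = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(100)],
            "grade": np.repeat([0, 1, 2, 3], 25),
            "noise": rng.normal(size=100),
        }
    )
    rep = evaluate_table(table, ["noise"], "grade")
    auc = rep.table.loc["01vs.23", "noise"]
    assert 0.35 <= auc <= 0.65


def test_evaluate_table_unknown_column_is_an_error():
    table = pd.DataFrame({"sample_id": ["a", "b", "c"], "stage": [0, 1, 2], "x": [1, 2, 3]})
    with pytest.raises(KeyError):
        evaluate_table(table, ["missing"], "stage")
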