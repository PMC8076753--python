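"""Dwell time, transitions, transition matrices, group comparison."""

import numpy as np
import pandas as pd
import pytest

from trajstates import compare_groups, mean_dwell_time, subject_metrics, transition_matrix, transition_number
from trajstates.metrics import benjamini_hochberg, run_lengths
from trajstates.states import StateSequence


def test_dwell_hand_example():
    d = mean_dwell_time(np.array([1, 1, 2, 2, 2, 1]), k=2)
    assert d[0] == pytest.approx(1.5)  # runs of 2 and 1
    assert d[1] == pytest.approx(3.0)


def test_dwell_constant_and_alternating():
    d = mean_dwell_time(np.ones(10, dtype=int), k=3)
    assert d[0] == 10 and np.isnan(d[1]) and np.isnan(d[2])
    alt = np.tile([1, 2], 10)
    np.testing.assert_array_equal(mean_dwell_time(alt, 2), [1.0, 1.0])


def test_run_lengths_order():
    assert run_lengths(np.array([3, 3, 1, 2, 2, 2])) == [(3, 2), (1, 1), (2, 3)]


def test_transition_number_examples():
    assert transition_number(np.array([1, 1, 2, 2, 2, 1])) == 2
    assert transition_number(np.ones(7, dtype=int)) == 0
    assert transition_number(np.tile([1, 2], 25)) == 49


def test_transition_matrix_hand_example():
    m = transition_matrix(np.array([1, 2, 2, 3]), k=3, lag=1)
    expected = np.zeros((3, 3), dtype=int)
    expected[0, 1] = expected[1, 1] = expected[1, 2] = 1
    np.testing.assert_array_equal(m, expected)


def test_transition_matrix_sums_and_constant():
    rng = np.random.default_rng(0)
    for _ in range(50):
        labels = rng.integers(1, 5, size=rng.integers(5, 60))
        for lag in (1, 2, 3):
            if lag >= labels.size:
                continue
            assert transition_matrix(labels, 4, lag).sum() == labels.size - lag
    const = np.full(9, 2)
    m = transition_matrix(const, 3, lag=2)
    assert m[1, 1] == 7 and m.sum() == 7


def test_transition_matrix_lag_validation():
    with pytest.raises(ValueError, match="lag"):
        transition_matrix(np.array([1, 2, 1]), 2, lag=3)
    with pytest.raises(ValueError, match="lag"):
        transition_matrix(np.array([1, 2, 1]), 2, lag=0)


def test_offdiagonal_sum_equals_transition_number():
    rng = np.random.default_rng(1)
    for _ in range(200):
        labels = rng.integers(1, 6, size=rng.integers(3, 80))
        m = transition_matrix(labels, 5, lag=1)
        assert m.sum() - np.trace(m) == transition_number(labels)


def test_reversal_symmetry():
    rng = np.random.default_rng(2)
    for _ in range(100):
        labels = rng.integers(1, 4, size=30)
        np.testing.assert_array_equal(
            transition_matrix(labels[::-1], 3, lag=1), transition_matrix(labels, 3, lag=1).T
        )


def test_occupancy_conservation():
    rng = np.random.default_rng(3)
    for _ in range(200):
        labels = rng.integers(1, 5, size=rng.integers(3, 100))
        occ = np.bincount(labels, minlength=5)[1:]
        assert occ.sum() == labels.size
        # dwell * run-count conservation
        d = mean_dwell_time(labels, 4)
        runs = run_lengths(labels)
        n_runs = np.bincount([s for s, _ in runs], minlength=5)[1:]
        total = np.nansum(np.where(n_runs > 0, d * n_runs, 0.0))
        assert total == pytest.approx(labels.size)


def test_bh_hand_example():
    adj = benjamini_hochberg(np.array([0.001, 0.02, 0.04, 0.8]))
    np.testing.assert_allclose(adj, [0.004, 0.04, 0.8 / 15, 0.8], rtol=1e-12)


def _bh_brute(p):
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def test_bh_matches_step_up_oracle():
    rng = np.random.default_rng(4)
    for _ in range(50):
        p = rng.uniform(size=rng.integers(1, 30))
        np.testing.assert_allclose(benjamini_hochberg(p), _bh_brute(p), rtol=1e-12)


def _metrics_frame(seqs_by_subject, k, lag=1):
    seq = StateSequence(labels={s: np.asarray(v) for s, v in seqs_by_subject.items()}, k=k)
    return subject_metrics(seq, lag=lag)


def test_subject_metrics_columns_and_values():
    df = _metrics_frame({"a": [1, 1, 2, 2, 2, 1]}, k=2)
    row = df.loc["a"]
    assert row["dwell_1"] == pytest.approx(1.5)
    assert row["dwell_2"] == pytest.approx(3.0)
    assert row["n_transitions"] == 2
    assert row["trans_1_2"] == 1 and row["trans_2_1"] == 1 and row["trans_2_2"] == 2


def test_compare_identical_groups_gives_p_one(rng):
    seqs = {}
    for i in range(4):
        labels = rng.integers(1, 4, size=50)
        seqs[f"g1_{i}"] = labels
        seqs[f"g2_{i}"] = labels.copy()  # duplicated data
    df = _metrics_frame(seqs, k=3)
    groups = {s: ("A" if s.startswith("g1") else "B") for s in seqs}
    comp = compare_groups(df, groups, alpha=0.01)
    assert np.allclose(comp["p_raw"], 1.0)
    assert not comp["significant"].any()


def _markov_labels(rng, T, k, stay, boost_state=None, boost_stay=None):
    labels = np.empty(T, dtype=int)
    labels[0] = rng.integers(1, k + 1)
    for t in range(1, T):
        cur = labels[t - 1]
        p_stay = boost_stay if (boost_state is not None and cur == boost_state) else stay
        if rng.random() < p_stay:
            labels[t] = cur
        else:
            others = [s for s in range(1, k + 1) if s != cur]
            labels[t] = others[rng.integers(len(others))]
    return labels


def test_dwell_difference_detected_with_power():
    # group B has a doubled self-transition probability in state 1
    rng = np.random.default_rng(5)
    detected = 0
    reps = 10
    for _ in range(reps):
        seqs, groups = {}, {}
        for i in range(50):
            seqs[f"a{i}"] = _markov_labels(rng, 150, 3, stay=0.4)
            groups[f"a{i}"] = "HC"
            seqs[f"b{i}"] = _markov_labels(rng, 150, 3, stay=0.4, boost_state=1, boost_stay=0.8)
            groups[f"b{i}"] = "SZ"
        comp = compare_groups(_metrics_frame(seqs, k=3), groups, alpha=0.01)
        row = comp[comp["metric"] == "dwell_1"].iloc[0]
        detected += bool(row["significant"])
    assert detected >= 9  # >= 90% of replicates


def test_unvisited_state_excluded_with_warning():
    seqs = {f"a{i}": np.tile([1, 2], 25) for i in range(3)}
    seqs.update({f"b{i}": np.tile([1, 2], 25) for i in range(3)})
    # one B subject visits state 3, the others never do
    seqs["b0"] = np.array([1, 2] * 24 + [3, 3])
    df = _metrics_frame(seqs, k=3)
    groups = {s: ("A" if s.startswith("a") else "B") for s in seqs}
    with pytest.warns(RuntimeWarning, match="missing for more than half"):
        comp = compare_groups(df, groups)
    assert "dwell_3" not in set(comp["metric"])


def test_adjusted_p_at_least_raw():
    rng = np.random.default_rng(6)
    seqs = {f"s{i}": rng.integers(1, 4, size=60) for i in range(12)}
    groups = {f"s{i}": ("A" if i < 6 else "B") for i in range(12)}
    comp = compare_groups(_metrics_frame(seqs, k=3), groups)
    assert np.all(comp["p_fdr"] >= comp["p_raw"] - 1e-12)


def test_mann_whitney_option(rng):
    seqs = {f"s{i}": rng.integers(1, 3, size=40) for i in range(8)}
    groups = {f"s{i}": ("A" if i < 4 else "B") for i in range(8)}
    comp = compare_groups(_metrics_frame(seqs, k=2), groups, test="mannwhitney")
    assert (comp["p_raw"] <= 1).all() and (comp["p_raw"] >= 0).all()
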