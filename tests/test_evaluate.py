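"""Holdout splits, ranking metrics, benchmark harness, and bounds."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import average_precision_score, roc_auc_score

from bilink import (
    BipartiteNetwork,
    HoldoutSplit,
    ScoreTable,
    extrapolate_auroc,
    get_predictor,
    make_holdout,
    missing_edge_bound,
    pr_metrics,
    precision_correction,
    roc_auc,
    run_benchmark,
    uniform_random_scores,
)

from conftest import random_bipartite


def _split_from_scores(pos_scores, neg_scores):
    """A 1-drug network whose non-edges carry the given scores: positives
    first, then negatives (distinct diseases)."""
    npos, nneg = len(pos_scores), len(neg_scores)
    nz = npos + nneg + 1
    # original network: edge to the last disease plus the positives
    orig_edges = {(0, nz - 1)} | {(0, j) for j in range(npos)}
    orig = BipartiteNetwork(("d",), tuple(f"z{j}" for j in range(nz)), frozenset(orig_edges))
    training = orig.remove_edges({(0, j) for j in range(npos)})
    pos = np.array([[0, j] for j in range(npos)], dtype=np.int64)
    neg = np.array([[0, j] for j in range(npos, npos + nneg)], dtype=np.int64)
    matrix = np.zeros((1, nz))
    matrix[0, :npos] = pos_scores
    matrix[0, npos : npos + nneg] = neg_scores
    table = ScoreTable.from_matrix(matrix, training)
    return table, HoldoutSplit(training, pos, neg)


# ------------------------------------------------------------ holdout ----

def test_make_holdout_counts_and_partition():
    net = random_bipartite(30, 20, 0.2, seed=1)
    split = make_holdout(net, 0.10, seed=3)
    assert len(split.positives) == int(np.rint(0.10 * net.m))
    assert split.positives | split.training.edges == net.edges
    assert split.positives.isdisjoint(split.training.edges)
    assert split.negatives.isdisjoint(net.edges)
    assert split.positives.isdisjoint(split.negatives)


def test_make_holdout_full_scale_positive_count(full_scale_net):
    """10% of 8946 edges rounds to 895 removed positives."""
    split = make_holdout(full_scale_net, 0.10, seed=0)
    assert len(split.positive_array()) == 895
    assert len(split.negative_array()) == 4363834


def test_make_holdout_deterministic():
    net = random_bipartite(25, 15, 0.25, seed=2)
    a = make_holdout(net, 0.1, seed=9)
    b = make_holdout(net, 0.1, seed=9)
    np.testing.assert_array_equal(a.positive_array(), b.positive_array())
    assert a.training.edges == b.training.edges


def test_make_holdout_zero_removals_rejected(toy_t1):
    with pytest.raises(ValueError, match="zero"):
        make_holdout(toy_t1, 0.01, seed=0)


# ------------------------------------------------------------ metrics ----

def test_roc_auc_hand_cases():
    t, s = _split_from_scores([3, 1], [2, 0])
    assert roc_auc(t, s) == pytest.approx(3 / 4)  # 3 of 4 comparisons won
    t, s = _split_from_scores([5, 4], [3, 2, 1])
    assert roc_auc(t, s) == 1.0
    t, s = _split_from_scores([1, 1], [1, 1, 1])
    assert roc_auc(t, s) == pytest.approx(0.5)  # all ties count one half


def test_roc_auc_matches_sklearn_and_trapezoid():
    """Rank-statistic AUROC equals explicit trapezoidal ROC integration
    (two independent implementations agree to 1e-12)."""
    rng = np.random.default_rng(0)
    for trial in range(5):
        pos = rng.normal(0.5, 1, size=40)
        neg = rng.normal(0, 1, size=150)
        t, s = _split_from_scores(pos, neg)
        ours = roc_auc(t, s)
        y = np.concatenate([np.ones(40), np.zeros(150)])
        x = np.concatenate([pos, neg])
        assert ours == pytest.approx(roc_auc_score(y, x), abs=1e-12)
        # explicit trapezoid over the threshold sweep
        order = np.argsort(-x, kind="stable")
        tp = np.cumsum(y[order])
        fp = np.cumsum(1 - y[order])
        tpr = np.concatenate([[0], tp / 40])
        fpr = np.concatenate([[0], fp / 150])
        assert ours == pytest.approx(np.trapezoid(tpr, fpr), abs=1e-12)


def test_pr_metrics_worked_example():
    """Ranking (+,-,+,-,-,+): precisions at the positives are 1, 2/3, 1/2,
    so average precision is 72.2%."""
    t, s = _split_from_scores([6, 4, 1], [5, 3, 2])
    aupr, npr, topk = pr_metrics(t, s, k=2)
    assert aupr == pytest.approx(100 * (1 + 2 / 3 + 1 / 2) / 3, abs=1e-9)
    assert round(aupr, 1) == 72.2
    assert npr == pytest.approx((aupr / 100) / 0.5)
    assert topk == pytest.approx(50.0)  # one hit in the top 2


def test_pr_metrics_perfect_ranking():
    t, s = _split_from_scores([9, 8, 7], [1, 2, 3])
    aupr, npr, topk = pr_metrics(t, s, k=3)
    assert aupr == 100.0
    assert topk == 100.0
    assert npr == pytest.approx(1 / s.prevalence)


def test_pr_metrics_matches_sklearn_average_precision():
    rng = np.random.default_rng(3)
    pos = rng.normal(0.8, 1, size=25)
    neg = rng.normal(0, 1, size=90)
    t, s = _split_from_scores(pos, neg)
    aupr, _, _ = pr_metrics(t, s, k=10)
    y = np.concatenate([np.ones(25), np.zeros(90)])
    x = np.concatenate([pos, neg])
    assert aupr / 100 == pytest.approx(average_precision_score(y, x), abs=1e-12)


def test_pr_metrics_k_too_large():
    t, s = _split_from_scores([1], [0])
    with pytest.raises(ValueError, match="exceeds"):
        pr_metrics(t, s, k=5)


# ---------------------------------------------------------- benchmark ----

def _oracle_predictor(original: BipartiteNetwork):
    """Scores 1 on every original edge (so all removed positives), else 0."""
    B = original.incidence_matrix()

    def predict(training, seed):
        return ScoreTable.from_matrix(B.copy(), training)

    return predict


def test_benchmark_oracle_predictor_is_perfect():
    net = random_bipartite(30, 20, 0.2, seed=4)
    reports = run_benchmark(
        net, {"oracle": _oracle_predictor(net)}, fraction=0.1, n_reps=4, k=5, seed=0
    )
    r = reports["oracle"]
    assert (r.per_rep["auroc"] == 1.0).all()
    assert (r.per_rep["aupr_pct"] == 100.0).all()
    assert (r.per_rep["topk_pct"] == 100.0).all()


def test_benchmark_deterministic_and_paired():
    net = random_bipartite(40, 30, 0.15, seed=5)
    preds = {"degree": get_predictor("degree"), "jaccard": get_predictor("jaccard")}
    a = run_benchmark(net, preds, fraction=0.1, n_reps=3, k=10, seed=7)
    b = run_benchmark(net, preds, fraction=0.1, n_reps=3, k=10, seed=7)
    for name in preds:
        pd.testing.assert_frame_equal(
            a[name].per_rep.drop(columns="seconds"),
            b[name].per_rep.drop(columns="seconds"),
        )


def test_benchmark_records_predictor_failures():
    net = random_bipartite(20, 20, 0.2, seed=6)

    def flaky(training, seed):
        raise RuntimeError("boom")

    reports = run_benchmark(
        net,
        {"flaky": flaky, "degree": get_predictor("degree")},
        fraction=0.1,
        n_reps=2,
        k=5,
        seed=1,
    )
    assert len(reports["flaky"].failures) == 2
    assert len(reports["flaky"].per_rep) == 0
    assert len(reports["degree"].per_rep) == 2


def test_benchmark_requires_predictor(toy_t1):
    with pytest.raises(ValueError, match="at least one"):
        run_benchmark(toy_t1, {}, n_reps=1)


# -------------------------------------------------------------- bounds ----

def test_missing_edge_bound_headline_numbers():
    est = missing_edge_bound(0.967, 4363834, 8946, measured_precision=20.0)
    assert est.mu_max == pytest.approx(0.066, abs=1e-12)
    assert est.nu_max == pytest.approx(0.066, abs=1e-12)
    assert est.max_missing_pairs == 288013  # "about 288 000"
    assert est.max_false_positives == 590
    lo, hi = est.precision_interval
    assert lo == 20.0
    assert round(hi, 1) == 21.4


def test_missing_edge_bound_edge_cases():
    perfect = missing_edge_bound(1.0, 1000, 100)
    assert perfect.mu_max == perfect.max_missing_pairs == perfect.max_false_positives == 0
    assert missing_edge_bound(0.75, 10, 10).mu_max == pytest.approx(0.5)
    with pytest.raises(ValueError, match="AUROC"):
        missing_edge_bound(0.3, 10, 10)


def test_precision_correction():
    assert precision_correction(20.0, 0.0) == (20.0, 20.0)
    lo, hi = precision_correction(50.0, 0.5)
    assert (lo, hi) == (50.0, 100.0)
    with pytest.raises(ValueError):
        precision_correction(10.0, 1.0)


def test_extrapolate_auroc_line_fit():
    # unweighted fit through near-collinear points; frozen from the
    # normal-equations oracle (np.polyfit)
    intercept, se = extrapolate_auroc([0.10, 0.05, 0.02], [0.94, 0.95, 0.962])
    oracle = np.polyfit([0.10, 0.05, 0.02], [0.94, 0.95, 0.962], 1)[1]
    assert intercept == pytest.approx(oracle, abs=1e-12)
    assert round(intercept, 3) == 0.966
    assert se > 0


def test_extrapolate_two_points_exact():
    intercept, se = extrapolate_auroc([0.1, 0.2], [0.9, 0.8])
    assert intercept == pytest.approx(1.0, abs=1e-12)
    assert se == 0.0


def test_extrapolate_weighted_matches_closed_form():
    x = np.array([0.1, 0.05, 0.02])
    y = np.array([0.94, 0.952, 0.960])
    se = np.array([0.002, 0.001, 0.003])
    b0, b0_se = extrapolate_auroc(x, y, se)
    w = 1 / se**2
    X = np.column_stack([np.ones(3), x])
    cov = np.linalg.inv(X.T @ np.diag(w) @ X)
    beta = cov @ X.T @ np.diag(w) @ y
    assert b0 == pytest.approx(beta[0], abs=1e-12)
    assert b0_se == pytest.approx(np.sqrt(cov[0, 0]), abs=1e-12)


def test_extrapolate_degenerate_inputs():
    with pytest.raises(ValueError, match="equal"):
        extrapolate_auroc([0.1, 0.1], [0.9, 0.91])
    with pytest.raises(ValueError, match="two"):
        extrapolate_auroc([0.1], [0.9])


def test_uniform_random_scores_deterministic(toy_t1):
    a = uniform_random_scores(toy_t1, seed=5)
    b = uniform_random_scores(toy_t1, seed=5)
    np.testing.assert_array_equal(a.matrix, b.matrix)
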