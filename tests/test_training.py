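"""OLS fitting, backwards elimination, cross-validation, metrics, scans."""

import numpy as np
import pandas as pd
import pytest

from mutddg.synth import make_linear_dataset
from mutddg.training import (
    backwards_eliminate,
    cross_validate,
    fit_weights,
    mcc,
    metrics,
    pearson_r,
    scan_dielectrics,
)


def test_noiseless_fit_is_exact():
    X, y = make_linear_dataset({"x1": 2.0, "x2": -3.0}, intercept=1.0,
                               noise_sd=0.0, n=50, seed=0)
    res = fit_weights(X, y)
    assert res.weights["x1"] == pytest.approx(2.0, abs=1e-8)
    assert res.weights["x2"] == pytest.approx(-3.0, abs=1e-8)
    assert res.intercept == pytest.approx(1.0, abs=1e-8)
    assert res.r == pytest.approx(1.0, abs=1e-9)


def test_noisy_fit_recovers_within_3_se():
    truth = {"x1": 1.5, "x2": -0.7, "x3": 0.3}
    X, y = make_linear_dataset(truth, intercept=0.5, noise_sd=0.5, n=500, seed=42)
    res = fit_weights(X, y)
    se = 0.5 / np.sqrt(500)  # noise / sqrt(n), unit-variance features
    for term, w in truth.items():
        assert abs(res.weights[term] - w) < 3.5 * se


def test_underdetermined_raises():
    X, y = make_linear_dataset({f"x{i}": 1.0 for i in range(10)},
                               intercept=0.0, noise_sd=0.0, n=8, seed=1)
    with pytest.raises(ValueError):
        fit_weights(X, y)


def test_constant_column_rejected():
    X = pd.DataFrame({"x1": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0], "x2": 1.0})
    with pytest.raises(ValueError, match="constant"):
        fit_weights(X, np.arange(6.0))


def test_collinear_columns_named():
    rng = np.random.default_rng(0)
    a = rng.normal(size=50)
    X = pd.DataFrame({"a": a, "b": 2 * a, "c": rng.normal(size=50)})
    with pytest.raises(ValueError, match="collinear"):
        fit_weights(X, rng.normal(size=50))


def test_residuals_orthogonal_to_columns():
    X, y = make_linear_dataset({"x1": 1.0, "x2": 2.0}, intercept=-1.0,
                               noise_sd=1.0, n=200, seed=5)
    res = fit_weights(X, y)
    pred = X.to_numpy() @ np.array([res.weights[c] for c in X.columns]) + res.intercept
    resid = y - pred
    for c in X.columns:
        assert abs(resid @ X[c].to_numpy()) < 1e-6 * np.linalg.norm(y)


def test_elimination_removes_noise_column():
    truth = {"x1": 1.5, "x2": -0.7}
    X, y = make_linear_dataset(truth, intercept=0.0, noise_sd=0.5, n=500, seed=7)
    rng = np.random.default_rng(8)
    X = X.assign(noise=rng.normal(size=len(X)))
    res = backwards_eliminate(X, y)
    assert set(res.terms) == {"x1", "x2"}
    assert [t for t, _ in res.elimination_trace] == ["noise"]
    assert all(p < 0.05 for p in res.pvalues.values())


def test_elimination_identity_when_all_significant():
    X, y = make_linear_dataset({"x1": 2.0, "x2": -1.0}, intercept=0.0,
                               noise_sd=0.1, n=300, seed=9)
    res = backwards_eliminate(X, y)
    assert res.elimination_trace == []
    assert set(res.terms) == {"x1", "x2"}


def test_elimination_deterministic():
    X, y = make_linear_dataset({"x1": 0.05, "x2": 1.0}, intercept=0.0,
                               noise_sd=1.0, n=100, seed=10)
    r1 = backwards_eliminate(X, y)
    r2 = backwards_eliminate(X, y)
    assert r1.elimination_trace == r2.elimination_trace
    assert r1.terms == r2.terms


def test_cv_noiseless_r_is_one():
    X, y = make_linear_dataset({"x1": 1.0, "x2": 2.0}, intercept=0.3,
                               noise_sd=0.0, n=100, seed=11)
    mean_r, fold_r = cross_validate(X, y, k=5, seed=0)
    assert mean_r == pytest.approx(1.0, abs=1e-9)
    assert len(fold_r) == 5


def test_cv_pure_noise_near_zero():
    rng = np.random.default_rng(12)
    X = pd.DataFrame({"x1": rng.normal(size=500), "x2": rng.normal(size=500)})
    y = rng.normal(size=500)
    mean_r, _ = cross_validate(X, y, k=5, seed=0)
    assert abs(mean_r) < 0.2


def test_cv_seeded_reproducibility():
    X, y = make_linear_dataset({"x1": 1.0}, intercept=0.0, noise_sd=1.0,
                               n=60, seed=13)
    assert cross_validate(X, y, 5, seed=3) == cross_validate(X, y, 5, seed=3)
    with pytest.raises(ValueError):
        cross_validate(X, y, k=61, seed=0)


def test_metrics_perfect_prediction():
    y = np.array([1.0, 2.0, 3.0, -1.0])
    m = metrics(y, y)
    assert m["r"] == pytest.approx(1.0)
    assert m["slope"] == pytest.approx(1.0)
    assert m["intercept"] == pytest.approx(0.0, abs=1e-12)


def test_mcc_perfect_and_hand_example():
    assert mcc(50, 50, 0, 0) == pytest.approx(1.0)
    tp, tn, fp, fn = 40, 45, 5, 10
    closed = mcc(tp, tn, fp, fn)
    # brute-force cross-check: correlation of the label vectors
    y_true = [1] * tp + [0] * tn + [0] * fp + [1] * fn
    y_pred = [1] * tp + [0] * tn + [1] * fp + [0] * fn
    assert closed == pytest.approx(pearson_r(y_true, y_pred), abs=1e-12)


def test_mcc_degenerate_returns_zero():
    assert mcc(10, 0, 0, 0) == 0.0
    with pytest.raises(ValueError):
        mcc(-1, 0, 0, 0)


def test_scan_harness_plumbing():
    rng = np.random.default_rng(20)
    base = pd.DataFrame(rng.normal(size=(10, 3)), columns=["dd_ee", "dd_ve", "dd_sp"])
    y = rng.normal(size=10)

    def feature_fn(triple):
        ec, ep, eo = triple
        return base / ec  # trivial dependence

    surf = scan_dielectrics(feature_fn, y, [10.0, 20.0], [20.0, 30.0], [20.0])
    assert len(surf) == 4
    assert np.isfinite(surf["r"]).all()

    surf0 = scan_dielectrics(feature_fn, np.ones(10), [10.0], [20.0], [20.0])
    assert surf0["degenerate"].all()
    assert (surf0["r"] == 0.0).all()
    with pytest.raises(ValueError):
        scan_dielectrics(feature_fn, y, [], [20.0], [20.0])


def test_scan_recovers_generating_dielectric():
    """Self-consistency: data generated at one dielectric triple correlates
    best when refit at that triple (coarse grid)."""
    rng = np.random.default_rng(21)
    n = 60
    # two independent charge-interaction components whose mixture in the
    # computed EE feature depends on the charged-group dielectric
    comp_a = rng.normal(size=n)
    comp_b = rng.normal(size=n)
    other = pd.DataFrame(
        rng.normal(size=(n, 2)), columns=["dd_ve", "dd_sp"]
    )
    true_eps = 20.0

    def feature_fn(triple):
        ec, _, _ = triple
        out = other.copy()
        out["dd_ee"] = comp_a / ec + comp_b / (ec + 60.0)
        return out

    feats = feature_fn((true_eps, 20.0, 20.0))
    y = 3.0 * feats["dd_ee"].to_numpy() + 0.5 * other["dd_ve"].to_numpy()
    y = y + rng.normal(scale=0.02, size=n)

    surf = scan_dielectrics(feature_fn, y, [5.0, 20.0, 60.0], [20.0], [20.0])
    best = surf.loc[surf["r"].idxmax()]
    assert best["eps_charged"] == true_eps
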