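"""Weight fitting and validation: OLS with classical t-test p-values,
backwards elimination at alpha = 0.05, seeded k-fold cross-validation,
regression/classification metrics, and the dielectric-scan harness.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .scoring import WeightSet

logger = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass
class RegressionResult:
    terms: List[str]
    intercept: float
    weights: Dict[str, float]
    pvalues: Dict[str, float]
    r: float
    n: int
    elimination_trace: List[Tuple[str, float]] = field(default_factory=list)
    cv_r: float | None = None
    cv_fold_r: List[float] = field(default_factory=list)

    def to_weight_set(self, regime: str) -> WeightSet:
        return WeightSet(
            regime, self.intercept, dict(self.weights), dict(self.pvalues),
            provenance="refit",
        )


def _check_design(X: pd.DataFrame, y: np.ndarray) -> None:
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (n={n}, p={p})")
    const = [c for c in X.columns if np.ptp(X[c].to_numpy(float)) == 0.0]
    if const:
        raise ValueError(f"constant feature columns: {const}")


def fit_weights(X: pd.DataFrame, y: Sequence[float]) -> RegressionResult:
    """Ordinary least squares with intercept; two-sided t-test p-values."""
    y = np.asarray(y, float)
    _check_design(X, y)
    design = sm.add_constant(X.astype(float), has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        corr = X.astype(float).corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.stack().idxmax()
        raise ValueError(
            f"rank-deficient design; most collinear columns: {worst}"
        )
    fit = sm.OLS(y, design).fit()
    pred = fit.fittedvalues
    r = pearson_r(y, np.asarray(pred))
    return RegressionResult(
        terms=list(X.columns),
        intercept=float(fit.params["const"]),
        weights={c: float(fit.params[c]) for c in X.columns},
        pvalues={c: float(fit.pvalues[c]) for c in X.columns},
        r=r,
        n=len(y),
    )


def backwards_eliminate(
    X: pd.DataFrame, y: Sequence[float], alpha: float = ALPHA
) -> RegressionResult:
    """Iteratively drop the least significant term (highest p >= alpha) and
    refit until every retained term has p < alpha.  The intercept is never
    removed."""
    cols = list(X.columns)
    trace: List[Tuple[str, float]] = []
    while True:
        res = fit_weights(X[cols], y)
        worst = max(cols, key=lambda c: res.pvalues[c])
        if res.pvalues[worst] < alpha or len(cols) == 1:
            res.elimination_trace = trace
            return res
        trace.append((worst, res.pvalues[worst]))
        logger.info("eliminating %s (p=%.3g)", worst, res.pvalues[worst])
        cols.remove(worst)


def cross_validate(
    X: pd.DataFrame, y: Sequence[float], k: int = 5, seed: int = 0
) -> Tuple[float, List[float]]:
    """Seeded shuffle, k contiguous folds; returns (mean fold R, per-fold R)."""
    y = np.asarray(y, float)
    n = len(y)
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    rs: List[float] = []
    for f in folds:
        test = np.zeros(n, bool)
        test[f] = True
        res = fit_weights(X[~test], y[~test])
        pred = (
            X[test].to_numpy(float) @ np.array([res.weights[c] for c in X.columns])
            + res.intercept
        )
        rs.append(pearson_r(y[test], pred))
    return float(np.mean(rs)), rs


def pearson_r(y_true: Sequence[float], y_pred: Sequence[float]) -> float:
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    st = y_true.std()
    sp = y_pred.std()
    if st == 0.0 or sp == 0.0:
        logger.warning("degenerate input to pearson_r; returning 0")
        return 0.0
    return float(np.corrcoef(y_true, y_pred)[0, 1])


def metrics(y_true: Sequence[float], y_pred: Sequence[float]) -> Dict[str, float]:
    """Pearson R plus slope/intercept of the y_true ~ y_pred regression line."""
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch")
    r = pearson_r(y_true, y_pred)
    if y_pred.std() == 0.0:
        slope, intercept = 0.0, float(np.mean(y_true))
    else:
        slope, intercept = np.polyfit(y_pred, y_true, 1)
    return {"r": r, "slope": float(slope), "intercept": float(intercept)}


def mcc(tp: int, tn: int, fp: int, fn: int) -> float:
    """Matthews correlation coefficient; 0 (with a warning) when a marginal
    is empty and the denominator vanishes."""
    for v in (tp, tn, fp, fn):
        if v < 0:
            raise ValueError("confusion counts must be non-negative")
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0.0:
        logger.warning("MCC undefined (empty marginal); returning 0")
        return 0.0
    return (tp * tn - fp * fn) / denom


def scan_dielectrics(
    feature_fn: Callable[[Tuple[float, float, float]], pd.DataFrame],
    y: Sequence[float],
    eps_charged: Iterable[float],
    eps_polar: Iterable[float],
    eps_other: Iterable[float],
) -> pd.DataFrame:
    """Correlation surface over a grid of residue-class dielectric constants.

    `feature_fn` maps an (eps_charged, eps_polar, eps_other) triple to a
    feature table with the electrostatic terms recomputed; an EE+VE+SP
    regression is fitted at each grid point and its R recorded."""
    eps_c = list(eps_charged)
    eps_p = list(eps_polar)
    eps_o = list(eps_other)
    if not (eps_c and eps_p and eps_o):
        raise ValueError("empty dielectric grid")
    y = np.asarray(y, float)
    rows = []
    for ec in eps_c:
        for ep in eps_p:
            for eo in eps_o:
                X = feature_fn((ec, ep, eo))
                degenerate = y.std() == 0.0
                if degenerate:
                    r = 0.0
                else:
                    r = fit_weights(X, y).r
                rows.append(
                    {
                        "eps_charged": ec,
                        "eps_polar": ep,
                        "eps_other": eo,
                        "r": r,
                        "degenerate": degenerate,
                    }
                )
    return pd.DataFrame(rows)
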