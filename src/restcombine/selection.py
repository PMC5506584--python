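"""t-score feature ranking and grid-search selection with inner 10-fold CV.

For each feature type, features are ranked by the absolute pooled-variance
two-sample t-score on the training subjects.  A joint grid over the kept
percentage {1,5,...,50}, the SVM trade-off C in {2^-4..2^6} and the RBF
width gamma in {2^-10..2^3} is scored by stratified inner 10-fold CV; inside
every inner fold the ranking and the z-scoring statistics are recomputed on
that fold's training part only, so no validation subject influences the
selection.  The winning triple (ties broken toward the smaller percent, then
smaller C, then smaller gamma) and its inner accuracy Acc_m are recorded;
Acc_m is later reused as the basis of the combination weights.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "SelectionGrids",
    "SelectionResult",
    "tscore_rank",
    "count_from_percent",
    "grid_select",
]

DEFAULT_PERCENTS = (1, 5, 10, 15, 20, 25, 30, 35, 40, 45, 50)
DEFAULT_C_GRID = tuple(2.0 ** n for n in range(-4, 7))
DEFAULT_GAMMA_GRID = tuple(2.0 ** n for n in range(-10, 4))


@dataclass(frozen=True)
class SelectionGrids:
    """Search grids for the (percent, C, gamma) selection."""

    percents: tuple[float, ...] = DEFAULT_PERCENTS
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID
    inner_k: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.percents or not self.c_grid or not self.gamma_grid:
            raise ValueError("grids must be non-empty")
        if any(p <= 0 or p > 100 for p in self.percents):
            raise ValueError("percents must lie in (0, 100]")


@dataclass
class SelectionResult:
    """Outcome of the grid search for one feature type on one training set."""

    feature_type: str
    kept_indices: np.ndarray
    percent: float
    acc_m: float
    c: float
    gamma: float


def tscore_rank(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Feature indices sorted by decreasing |t| (pooled two-sample t-test).

    Ties (including zero-variance features, whose |t| is set to 0 with a
    warning) are broken by ascending feature index, making the ordering
    deterministic.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    a, b = X[y > 0], X[y < 0]
    n1, n2 = a.shape[0], b.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 samples in each class")
    v1 = a.var(axis=0, ddof=1)
    v2 = b.var(axis=0, ddof=1)
    pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    denom = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    zero = denom == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-variance features ranked last",
                      stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(a.mean(axis=0) - b.mean(axis=0)) / denom
    t[zero] = 0.0
    return np.argsort(-t, kind="stable")


def count_from_percent(percent: float, n_features: int) -> int:
    """ceil(percent * F / 100), but at least one feature."""
    if n_features < 1:
        raise ValueError("need at least one feature")
    return max(1, math.ceil(percent * n_features / 100.0))


def _zscore_stats(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return mu, sd


def _sq_dists(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances between rows of a and rows of b."""
    aa = (a * a).sum(axis=1)[:, None]
    bb = (b * b).sum(axis=1)[None, :]
    return np.maximum(aa + bb - 2.0 * a @ b.T, 0.0)


def grid_select(
    X: np.ndarray, y: np.ndarray, grids: SelectionGrids,
    feature_type: str = "",
) -> SelectionResult:
    """Joint (percent, C, gamma) grid search scored by inner stratified CV.

    Within each inner fold the t-score ranking and the standardisation are
    recomputed on the inner-training part only.  The returned kept indices
    are the top features re-ranked on the *full* training set at the chosen
    percent, ready for the outer-fold model fit.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, n_features = X.shape
    percents, cs, gammas = grids.percents, grids.c_grid, grids.gamma_grid
    correct = np.zeros((len(percents), len(cs), len(gammas)))

    skf = StratifiedKFold(n_splits=grids.inner_k, shuffle=True,
                          random_state=grids.seed)
    for train_idx, val_idx in skf.split(X, y):
        y_tr, y_va = y[train_idx], y[val_idx]
        if len(np.unique(y_tr)) < 2 or len(np.unique(y_va)) < 1:
            raise RuntimeError("stratification failed: class missing in fold")
        order = tscore_rank(X[train_idx], y_tr)
        mu, sd = _zscore_stats(X[train_idx])
        z_tr = (X[train_idx] - mu) / sd
        z_va = (X[val_idx] - mu) / sd
        for ip, pct in enumerate(percents):
            cols = order[:count_from_percent(pct, n_features)]
            a, b = z_tr[:, cols], z_va[:, cols]
            d_tt = _sq_dists(a, a)
            d_vt = _sq_dists(b, a)
            for ig, gamma in enumerate(gammas):
                k_tt = np.exp(-gamma * d_tt)
                k_vt = np.exp(-gamma * d_vt)
                for ic, c in enumerate(cs):
                    clf = SVC(kernel="precomputed", C=c)
                    clf.fit(k_tt, y_tr)
                    correct[ip, ic, ig] += (clf.predict(k_vt) == y_va).sum()

    acc = correct / n
    best = (-1.0, 0, 0, 0)
    for ip in range(len(percents)):
        for ic in range(len(cs)):
            for ig in range(len(gammas)):
                if acc[ip, ic, ig] > best[0]:
                    best = (acc[ip, ic, ig], ip, ic, ig)
    acc_m, ip, ic, ig = best
    pct = percents[ip]
    kept = tscore_rank(X, y)[:count_from_percent(pct, n_features)]
    return SelectionResult(
        feature_type=feature_type,
        kept_indices=np.asarray(kept),
        percent=pct,
        acc_m=float(acc_m),
        c=cs[ic],
        gamma=gammas[ig],
    )
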