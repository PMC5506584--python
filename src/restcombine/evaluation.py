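"""Balanced outer cross-validation, quality metrics, and selection
significance via a permutation empirical null.

The outer loop is a balanced stratified 10-fold CV: each fold holds out an
equal number of subjects from both classes, and *everything* — feature
ranking, the (percent, C, gamma) grid, standardisation, kernel weights —
is recomputed on the remaining training subjects only.  A leakage guard
aborts the run if any held-out subject reaches a selection call.

Classification quality on the pooled outer confusion counts:

    sensitivity = TP/(TP+FN)        specificity = TN/(TN+FP)
    accuracy    = (TP+TN)/total     precision   = TP/(TP+FP)
    F score     = 2TP/(2TP+FP+FN)

Selection significance: across folds (and frameworks) the number of times
each feature was kept is compared against an empirical null in which every
fold keeps a uniformly random feature subset of the same size; the observed
counts are thresholded at the smallest count whose null exceedance
probability is below alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from restcombine.features import FeatureSet, FEATURE_TYPE_ORDER
from restcombine.frameworks import (
    compute_weights,
    train_classifier_combination,
    train_feature_combination,
    train_kernel_combination,
    train_single_type,
)
from restcombine.selection import SelectionGrids, SelectionResult, grid_select

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "CVResult",
    "SignificanceResult",
    "LeakageError",
    "balanced_folds",
    "metrics",
    "assemble_matrices",
    "run_experiment",
    "selection_significance",
]

FRAMEWORKS = ("feature", "kernel", "classifier")


class LeakageError(RuntimeError):
    """A held-out subject reached a training/selection computation."""


@dataclass
class ConfusionCounts:
    """Binary confusion counts; group +1 is the positive class."""

    tp: int = 0
    fn: int = 0
    tn: int = 0
    fp: int = 0

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fn + other.fn,
                               self.tn + other.tn, self.fp + other.fp)

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass
class MetricsReport:
    sensitivity: float
    specificity: float
    accuracy: float
    precision: float
    f_score: float


@dataclass
class CVResult:
    """Outcome of one framework's balanced outer CV."""

    framework: str
    fold_counts: list[ConfusionCounts]
    pooled: ConfusionCounts
    selections: list[dict[str, SelectionResult]]  # per outer fold
    weights: list  # per outer fold CombinationWeights or None
    seed: int
    config: dict

    @property
    def metrics(self) -> MetricsReport:
        return metrics(self.pooled)


@dataclass
class SignificanceResult:
    """Permutation-null significance of per-feature selection counts."""

    feature_type: str
    observed_counts: np.ndarray
    threshold: int
    significant: np.ndarray  # boolean per feature
    n_repeats: int
    alpha: float


def balanced_folds(labels, k: int = 10, seed: int = 0) -> np.ndarray:
    """Stratified fold assignment with equal class counts per fold.

    Returns an integer fold id per subject.  Deterministic given the seed;
    per-class fold sizes differ by at most one (warned when not exactly
    balanced).
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    fold_of = np.empty(labels.size, dtype=int)
    for cls in np.unique(labels):
        idx = np.nonzero(labels == cls)[0]
        if idx.size < k:
            raise ValueError(f"class {cls} has fewer than k={k} subjects")
        if idx.size % k:
            warnings.warn(f"class {cls} size {idx.size} not divisible by "
                          f"k={k}; fold sizes differ by one", stacklevel=2)
        perm = rng.permutation(idx)
        for f, chunk in enumerate(np.array_split(perm, k)):
            fold_of[chunk] = f
    return fold_of


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """The five quality metrics from pooled confusion counts.

    Undefined ratios (0/0) are reported as 0 with a warning.
    """
    if min(counts.tp, counts.fn, counts.tn, counts.fp) < 0:
        raise ValueError("negative confusion counts")
    if counts.total == 0:
        raise ValueError("empty confusion counts")

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined (0/0); reporting 0",
                          stacklevel=3)
            return 0.0
        return num / den

    return MetricsReport(
        sensitivity=ratio(counts.tp, counts.tp + counts.fn, "sensitivity"),
        specificity=ratio(counts.tn, counts.tn + counts.fp, "specificity"),
        accuracy=(counts.tp + counts.tn) / counts.total,
        precision=ratio(counts.tp, counts.tp + counts.fp, "precision"),
        f_score=ratio(2 * counts.tp, 2 * counts.tp + counts.fp + counts.fn,
                      "F score"),
    )


def assemble_matrices(
    feature_sets: list[FeatureSet],
    feature_types: tuple[str, ...] | None = None,
) -> tuple[dict[str, np.ndarray], dict[str, tuple[str, ...]], np.ndarray]:
    """Stack per-subject feature vectors into per-type n x F matrices.

    Verifies that feature names align across subjects.  Returns
    (matrices, names, labels).
    """
    if feature_types is None:
        present = list(feature_sets[0].features.keys())
        canonical = tuple(t for t in FEATURE_TYPE_ORDER if t in present)
        extra = tuple(t for t in present if t not in FEATURE_TYPE_ORDER)
        feature_types = canonical + extra
    matrices: dict[str, np.ndarray] = {}
    names: dict[str, tuple[str, ...]] = {}
    for ft in feature_types:
        ref = feature_sets[0].features[ft].names
        rows = []
        for fs in feature_sets:
            fv = fs.features[ft]
            if fv.names != ref:
                raise ValueError(
                    f"feature name mismatch for {ft} in {fs.subject_id}")
            if not np.isfinite(fv.values).all():
                raise ValueError(
                    f"non-finite {ft} features for {fs.subject_id}")
            rows.append(fv.values)
        matrices[ft] = np.vstack(rows)
        names[ft] = ref
    y = np.asarray([fs.label for fs in feature_sets])
    return matrices, names, y


def _select_fold(
    matrices: dict[str, np.ndarray],
    y: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    grids: SelectionGrids,
) -> dict[str, SelectionResult]:
    """Per-type grid selection on training subjects, with a leakage guard."""
    if np.intersect1d(train_idx, test_idx).size:
        raise LeakageError("test subject index appeared in a selection call")
    out = {}
    for ft, X in matrices.items():
        out[ft] = grid_select(X[train_idx], y[train_idx], grids,
                              feature_type=ft)
    return out


def _count_confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    return ConfusionCounts(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        fn=int(((y_true == 1) & (y_pred == -1)).sum()),
        tn=int(((y_true == -1) & (y_pred == -1)).sum()),
        fp=int(((y_true == -1) & (y_pred == 1)).sum()),
    )


def run_experiment(
    feature_sets: list[FeatureSet],
    frameworks=FRAMEWORKS,
    grids: SelectionGrids | None = None,
    outer_k: int = 10,
    seed: int = 0,
    feature_types: tuple[str, ...] | None = None,
) -> dict[str, CVResult]:
    """Balanced outer k-fold CV of one or more frameworks.

    ``frameworks`` may contain "feature", "kernel", "classifier" and
    "single:<type>" tags.  Feature selection is performed once per outer
    fold on the training subjects and shared by all requested frameworks
    (they consume identical selection outputs by construction).
    """
    if isinstance(frameworks, str):
        frameworks = (frameworks,)
    if grids is None:
        grids = SelectionGrids()
    matrices, _, y = assemble_matrices(feature_sets, feature_types)
    types = tuple(matrices.keys())
    fold_of = balanced_folds(y, k=outer_k, seed=seed)

    fold_counts: dict[str, list[ConfusionCounts]] = {f: [] for f in frameworks}
    fold_weights: dict[str, list] = {f: [] for f in frameworks}
    all_selections: list[dict[str, SelectionResult]] = []

    for f in range(outer_k):
        test_idx = np.nonzero(fold_of == f)[0]
        train_idx = np.nonzero(fold_of != f)[0]
        sels = _select_fold(matrices, y, train_idx, test_idx, grids)
        all_selections.append(sels)
        y_tr, y_te = y[train_idx], y[test_idx]
        acc_vec = np.array([sels[t].acc_m for t in types])

        for fw in frameworks:
            if fw.startswith("single:"):
                ft = fw.split(":", 1)[1]
                model = train_single_type(matrices[ft][train_idx], y_tr,
                                          sels[ft])
                pred = model.predict(matrices[ft][test_idx])
                fold_weights[fw].append(None)
            elif fw == "feature":
                blocks_tr = [matrices[t][train_idx][:, sels[t].kept_indices]
                             for t in types]
                blocks_te = [matrices[t][test_idx][:, sels[t].kept_indices]
                             for t in types]
                model = train_feature_combination(blocks_tr, y_tr, grids)
                pred = model.predict(blocks_te)
                fold_weights[fw].append(None)
            elif fw == "kernel":
                weights = compute_weights(acc_vec)
                blocks_tr = [matrices[t][train_idx][:, sels[t].kept_indices]
                             for t in types]
                blocks_te = [matrices[t][test_idx][:, sels[t].kept_indices]
                             for t in types]
                gammas = [sels[t].gamma for t in types]
                model = train_kernel_combination(blocks_tr, y_tr, weights,
                                                 gammas, grids)
                pred = model.predict(blocks_te)
                fold_weights[fw].append(weights)
            elif fw == "classifier":
                weights = compute_weights(acc_vec)
                model = train_classifier_combination(
                    [matrices[t][train_idx] for t in types], y_tr,
                    [sels[t] for t in types], weights)
                pred = model.predict([matrices[t][test_idx] for t in types])
                fold_weights[fw].append(weights)
            else:
                raise ValueError(f"unknown framework tag: {fw}")
            fold_counts[fw].append(_count_confusion(y_te, pred))

    config = {
        "outer_k": outer_k,
        "feature_types": types,
        "grids": {
            "percents": grids.percents,
            "c_grid": grids.c_grid,
            "gamma_grid": grids.gamma_grid,
            "inner_k": grids.inner_k,
        },
    }
    results = {}
    for fw in frameworks:
        pooled = ConfusionCounts()
        for c in fold_counts[fw]:
            pooled = pooled + c
        results[fw] = CVResult(
            framework=fw,
            fold_counts=fold_counts[fw],
            pooled=pooled,
            selections=all_selections,
            weights=fold_weights[fw],
            seed=seed,
            config=config,
        )
    return results


def selection_significance(
    masks: list[np.ndarray],
    n_features: int,
    n_repeats: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    feature_type: str = "",
) -> SignificanceResult:
    """Empirical-null significance of per-feature selection counts.

    ``masks`` is one kept-index array per fold (pooled over frameworks,
    e.g. 3 frameworks x 10 folds = 30 entries).  Per null repeat, each fold
    draws a uniformly random feature subset of the same size as it actually
    kept; the per-feature null counts from all repeats are pooled into one
    empirical distribution.  The threshold is the smallest count c with
    P_null(count >= c) < alpha; features whose observed count reaches it
    are significant.
    """
    if n_repeats < 100:
        warnings.warn("fewer than 100 null repeats; threshold is unstable",
                      stacklevel=2)
    sizes = [len(m) for m in masks]
    observed = np.zeros(n_features, dtype=int)
    for m in masks:
        observed[np.asarray(m, dtype=int)] += 1

    rng = np.random.default_rng(seed)
    null_counts = np.zeros((n_repeats, n_features), dtype=np.int16)
    for rep in range(n_repeats):
        for size in sizes:
            draw = rng.choice(n_features, size=size, replace=False)
            null_counts[rep, draw] += 1

    n_folds = len(masks)
    flat = null_counts.ravel()
    total = flat.size
    exceed = np.array([(flat >= c).sum() / total
                       for c in range(n_folds + 2)])
    below = np.nonzero(exceed < alpha)[0]
    threshold = int(below[0]) if below.size else n_folds + 1
    return SignificanceResult(
        feature_type=feature_type,
        observed_counts=observed,
        threshold=threshold,
        significant=observed >= threshold,
        n_repeats=n_repeats,
        alpha=alpha,
    )
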