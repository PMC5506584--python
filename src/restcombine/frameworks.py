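"""The three fusion strategies around an RBF-SVM, plus single-type baselines.

* **Feature combination** — selected features of every type are concatenated
  into one vector per subject and a single RBF-SVM is trained, with (C,
  gamma) chosen by an inner stratified grid search.
* **Kernel combination** — one RBF Gram matrix per feature type (each with
  the gamma chosen during that type's selection) is linearly combined with
  accuracy-derived weights beta_m into a single valid kernel; only C is
  re-searched for the combined precomputed-kernel SVM.
* **Classifier combination** — one RBF-SVM per feature type, fused by
  weighted voting on the decision values: y = sign(sum_m beta_m f_m(x)).

The combining weights follow the accuracy heuristic

    beta_m = (Acc_m - 0.5) / sum_{i: Acc_i > 0.5} (Acc_i - 0.5)   if Acc_m > 0.5
    beta_m = 0                                                     otherwise

so feature types that did not beat chance in the inner CV are zeroed; if no
type beats chance the weights fall back to uniform (flagged).  sign(0) is
resolved to +1 by convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from restcombine.selection import SelectionGrids, SelectionResult, _zscore_stats

__all__ = [
    "CombinationWeights",
    "compute_weights",
    "rbf_gram",
    "combine_kernels",
    "weighted_vote",
    "SingleTypeModel",
    "FeatureCombinationModel",
    "KernelCombinationModel",
    "ClassifierCombinationModel",
    "train_single_type",
    "train_feature_combination",
    "train_kernel_combination",
    "train_classifier_combination",
]


@dataclass
class CombinationWeights:
    """Per-feature-type combining weights derived from inner-CV accuracies."""

    beta: np.ndarray
    source_acc: np.ndarray
    fallback_uniform: bool = False


def compute_weights(acc) -> CombinationWeights:
    """Accuracy-based combining weights (see module docstring).

    Types at or below chance (Acc <= 0.5, strict exclusion) get weight 0;
    if every type is at or below chance the weights are uniform and the
    result is flagged.
    """
    acc = np.asarray(acc, dtype=float)
    if acc.size == 0:
        raise ValueError("empty accuracy vector")
    if np.any((acc < 0) | (acc > 1)):
        raise ValueError("accuracies must lie in [0, 1]")
    above = acc > 0.5
    if not above.any():
        warnings.warn("no feature type beat chance; uniform weight fallback",
                      stacklevel=2)
        beta = np.full(acc.size, 1.0 / acc.size)
        return CombinationWeights(beta=beta, source_acc=acc,
                                  fallback_uniform=True)
    beta = np.where(above, acc - 0.5, 0.0)
    beta /= beta[above].sum()
    return CombinationWeights(beta=beta, source_acc=acc)


def rbf_gram(x1: np.ndarray, x2: np.ndarray, gamma: float) -> np.ndarray:
    """K[a, b] = exp(-gamma * ||x1_a - x2_b||^2)."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if not (np.isfinite(x1).all() and np.isfinite(x2).all()):
        raise ValueError("non-finite input to rbf_gram")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    aa = (x1 * x1).sum(axis=1)[:, None]
    bb = (x2 * x2).sum(axis=1)[None, :]
    d = np.maximum(aa + bb - 2.0 * x1 @ x2.T, 0.0)
    return np.exp(-gamma * d)


def combine_kernels(
    kernels: list[np.ndarray], weights: CombinationWeights
) -> np.ndarray:
    """Linear combination sum_m beta_m K^(m); PSD for PSD inputs."""
    if len(kernels) != weights.beta.size:
        raise ValueError("kernel count and weight count differ")
    shape = kernels[0].shape
    out = np.zeros(shape)
    for beta, k in zip(weights.beta, kernels):
        if k.shape != shape:
            raise ValueError("kernel shape mismatch")
        out += beta * k
    return out


def weighted_vote(panel: np.ndarray, weights: CombinationWeights) -> np.ndarray:
    """y_i = sign(sum_m beta_m f_m(x_i)); an exact zero becomes +1."""
    panel = np.asarray(panel, dtype=float)
    if not np.isfinite(panel).all():
        raise ValueError("non-finite decision value in panel")
    score = panel @ weights.beta
    labels = np.where(score >= 0, 1, -1)
    return labels.astype(int)


# ---------------------------------------------------------------------------
# trained models
# ---------------------------------------------------------------------------

@dataclass
class SingleTypeModel:
    """RBF-SVM on one feature type's selected, z-scored features."""

    columns: np.ndarray
    mu: np.ndarray
    sd: np.ndarray
    svc: SVC
    c: float
    gamma: float

    def _transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float)[:, self.columns] - self.mu) / self.sd

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self.svc.decision_function(self._transform(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.svc.predict(self._transform(X)).astype(int)


def train_single_type(
    X: np.ndarray, y: np.ndarray, sel: SelectionResult
) -> SingleTypeModel:
    """Fit the baseline model for one feature type at its selected
    (features, C, gamma)."""
    cols = sel.kept_indices
    block = np.asarray(X, dtype=float)[:, cols]
    mu, sd = _zscore_stats(block)
    svc = SVC(kernel="rbf", C=sel.c, gamma=sel.gamma)
    svc.fit((block - mu) / sd, y)
    return SingleTypeModel(columns=cols, mu=mu, sd=sd, svc=svc,
                           c=sel.c, gamma=sel.gamma)


@dataclass
class FeatureCombinationModel:
    """RBF-SVM on the concatenation of all selected feature blocks."""

    mu: np.ndarray
    sd: np.ndarray
    svc: SVC
    c: float
    gamma: float

    def predict(self, blocks: list[np.ndarray]) -> np.ndarray:
        z = (np.hstack(blocks) - self.mu) / self.sd
        return self.svc.predict(z).astype(int)

    def decision_function(self, blocks: list[np.ndarray]) -> np.ndarray:
        z = (np.hstack(blocks) - self.mu) / self.sd
        return self.svc.decision_function(z)


def train_feature_combination(
    blocks: list[np.ndarray], y: np.ndarray, grids: SelectionGrids
) -> FeatureCombinationModel:
    """Concatenate per-type selected blocks and train one RBF-SVM.

    (C, gamma) are chosen by inner stratified k-fold CV on the training
    subjects (z-scoring refit inside each inner fold); ties go to the
    smaller C, then smaller gamma.
    """
    if not blocks or sum(b.shape[1] for b in blocks) == 0:
        raise ValueError("empty feature concatenation")
    X = np.hstack(blocks)
    y = np.asarray(y)
    from sklearn.model_selection import StratifiedKFold

    correct = np.zeros((len(grids.c_grid), len(grids.gamma_grid)))
    skf = StratifiedKFold(n_splits=grids.inner_k, shuffle=True,
                          random_state=grids.seed)
    for tr, va in skf.split(X, y):
        mu, sd = _zscore_stats(X[tr])
        a = (X[tr] - mu) / sd
        b = (X[va] - mu) / sd
        d_tt = np.maximum(
            (a * a).sum(1)[:, None] + (a * a).sum(1)[None, :] - 2 * a @ a.T, 0)
        d_vt = np.maximum(
            (b * b).sum(1)[:, None] + (a * a).sum(1)[None, :] - 2 * b @ a.T, 0)
        for ig, gamma in enumerate(grids.gamma_grid):
            k_tt = np.exp(-gamma * d_tt)
            k_vt = np.exp(-gamma * d_vt)
            for ic, c in enumerate(grids.c_grid):
                clf = SVC(kernel="precomputed", C=c)
                clf.fit(k_tt, y[tr])
                correct[ic, ig] += (clf.predict(k_vt) == y[va]).sum()

    best = (-1.0, 0, 0)
    for ic in range(len(grids.c_grid)):
        for ig in range(len(grids.gamma_grid)):
            if correct[ic, ig] > best[0]:
                best = (correct[ic, ig], ic, ig)
    _, ic, ig = best
    c, gamma = grids.c_grid[ic], grids.gamma_grid[ig]
    mu, sd = _zscore_stats(X)
    svc = SVC(kernel="rbf", C=c, gamma=gamma)
    svc.fit((X - mu) / sd, y)
    return FeatureCombinationModel(mu=mu, sd=sd, svc=svc, c=c, gamma=gamma)


@dataclass
class KernelCombinationModel:
    """SVM on a precomputed convex combination of per-type RBF kernels."""

    weights: CombinationWeights
    gammas: np.ndarray
    mus: list[np.ndarray]
    sds: list[np.ndarray]
    train_blocks: list[np.ndarray]  # z-scored training blocks
    svc: SVC
    c: float

    def _combined_cross(self, blocks: list[np.ndarray]) -> np.ndarray:
        kernels = []
        for m, block in enumerate(blocks):
            z = (np.asarray(block, dtype=float) - self.mus[m]) / self.sds[m]
            kernels.append(rbf_gram(z, self.train_blocks[m], self.gammas[m]))
        return combine_kernels(kernels, self.weights)

    def predict(self, blocks: list[np.ndarray]) -> np.ndarray:
        return self.svc.predict(self._combined_cross(blocks)).astype(int)

    def decision_function(self, blocks: list[np.ndarray]) -> np.ndarray:
        return self.svc.decision_function(self._combined_cross(blocks))


def train_kernel_combination(
    blocks: list[np.ndarray],
    y: np.ndarray,
    weights: CombinationWeights,
    gammas,
    grids: SelectionGrids,
) -> KernelCombinationModel:
    """Combine per-type RBF kernels with weights beta and train on the mix.

    Each type's gamma is the one chosen during its selection step; only C
    is re-searched (inner stratified CV on the combined precomputed
    kernel).  Prediction applies the same per-type gammas and beta to the
    train-test cross-kernels.
    """
    gammas = np.asarray(gammas, dtype=float)
    y = np.asarray(y)
    mus, sds, ztrain = [], [], []
    for block in blocks:
        mu, sd = _zscore_stats(np.asarray(block, dtype=float))
        mus.append(mu)
        sds.append(sd)
        ztrain.append((block - mu) / sd)

    from sklearn.model_selection import StratifiedKFold

    correct = np.zeros(len(grids.c_grid))
    skf = StratifiedKFold(n_splits=grids.inner_k, shuffle=True,
                          random_state=grids.seed)
    for tr, va in skf.split(blocks[0], y):
        fold_k_tt, fold_k_vt = [], []
        for m, block in enumerate(blocks):
            mu, sd = _zscore_stats(block[tr])
            a = (block[tr] - mu) / sd
            b = (block[va] - mu) / sd
            fold_k_tt.append(rbf_gram(a, a, gammas[m]))
            fold_k_vt.append(rbf_gram(b, a, gammas[m]))
        k_tt = combine_kernels(fold_k_tt, weights)
        k_vt = combine_kernels(fold_k_vt, weights)
        for ic, c in enumerate(grids.c_grid):
            clf = SVC(kernel="precomputed", C=c)
            clf.fit(k_tt, y[tr])
            correct[ic] += (clf.predict(k_vt) == y[va]).sum()

    ic = int(np.argmax(correct))  # first maximum -> smallest C on ties
    c = grids.c_grid[ic]
    k_full = combine_kernels(
        [rbf_gram(z, z, g) for z, g in zip(ztrain, gammas)], weights)
    svc = SVC(kernel="precomputed", C=c)
    svc.fit(k_full, y)
    return KernelCombinationModel(weights=weights, gammas=gammas, mus=mus,
                                  sds=sds, train_blocks=ztrain, svc=svc, c=c)


@dataclass
class ClassifierCombinationModel:
    """Weighted-voting fusion of per-type SVM decision values."""

    models: list[SingleTypeModel]
    weights: CombinationWeights

    def decision_panel(self, type_matrices: list[np.ndarray]) -> np.ndarray:
        return np.column_stack(
            [m.decision_function(X) for m, X in zip(self.models, type_matrices)])

    def predict(self, type_matrices: list[np.ndarray]) -> np.ndarray:
        return weighted_vote(self.decision_panel(type_matrices), self.weights)


def train_classifier_combination(
    type_matrices: list[np.ndarray],
    y: np.ndarray,
    selections: list[SelectionResult],
    weights: CombinationWeights,
) -> ClassifierCombinationModel:
    """One RBF-SVM per feature type at its selected (features, C, gamma),
    fused by weighted voting at prediction time."""
    models = [train_single_type(X, y, sel)
              for X, sel in zip(type_matrices, selections)]
    return ClassifierCombinationModel(models=models, weights=weights)
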