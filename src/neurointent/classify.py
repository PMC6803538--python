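"""Intention classification: feature fusion, Relief-F selection, RBF-SVM.

EEG and fNIRS nodal feature tables are fused by column concatenation
(64*5 + 48*5 = 560 columns).  Within every training fold, features are
z-scored, ranked by Relief-F (k = 10 nearest hits/misses, Manhattan distance
on min-max-normalized features), the top ``n_keep`` are retained, and an
RBF-kernel C-SVC is fit with (C, gamma) chosen by an inner stratified grid
search.  Accuracy is the mean over 10 repetitions of stratified 10-fold
cross-validation (~25 training / 3 test trials per class for an 84-trial
run).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin, clone
from sklearn.model_selection import GridSearchCV, RepeatedStratifiedKFold, StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .network import NodalFeatureTable
from .sensor_stats import DegenerateDataError, bonferroni

DEFAULT_C_GRID = tuple(2.0**e for e in range(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(2.0**e for e in range(-15, 4, 2))


def fuse(*tables: NodalFeatureTable) -> NodalFeatureTable:
    """Column-concatenate feature tables over identical trial label sequences."""
    tables = [t for t in tables if t is not None and t.values.shape[1] > 0]
    if not tables:
        raise ValueError("nothing to fuse")
    first = tables[0]
    for t in tables[1:]:
        if not np.array_equal(t.labels, first.labels):
            raise ValueError("feature tables disagree on trial labels")
    return NodalFeatureTable(
        values=np.concatenate([t.values for t in tables], axis=1),
        columns=[c for t in tables for c in t.columns],
        labels=first.labels.copy(),
        modality="+".join(t.modality for t in tables),
    )


@dataclass(frozen=True)
class ReliefFConfig:
    k_neighbors: int = 10
    n_keep: int = 60
    sample_all: bool = True


class ReliefF(BaseEstimator, TransformerMixin):
    """Relief-F feature weighting and selection (multi-class).

    For each instance R of class c, the k nearest hits and, per other class
    c', the k nearest misses are found under Manhattan distance on
    min-max-normalized features.  Feature weights are updated

        W[f] -= sum_hits diff(f, R, H) / (m * k)
        W[f] += sum_{c'} P(c')/(1 - P(c)) * sum_miss diff(f, R, M) / (m * k)

    with diff(f, a, b) = |a_f - b_f| / range(f) and m the number of sampled
    instances (all of them by default).  Zero-range features get weight 0.
    Weights are invariant to affine feature rescaling because every distance
    and diff uses range-normalized values.

    Fitted attributes: ``weights_``, ``ranking_`` (feature indices by
    decreasing weight, ties broken by ascending index), ``top_indices_``.
    """

    def __init__(self, n_keep: int = 60, k_neighbors: int = 10,
                 sample_all: bool = True):
        self.n_keep = n_keep
        self.k_neighbors = k_neighbors
        self.sample_all = sample_all

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ReliefF":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        m, n_feat = X.shape
        classes, counts = np.unique(y, return_counts=True)
        if np.any(counts < self.k_neighbors + 1):
            warnings.warn(
                "a class has fewer than k+1 instances; using all available "
                "neighbors",
                stacklevel=2,
            )
        rng_range = X.max(axis=0) - X.min(axis=0)
        zero = rng_range <= 0
        if zero.any():
            warnings.warn(
                f"{int(zero.sum())} zero-range feature(s) get weight 0",
                stacklevel=2,
            )
        safe_range = np.where(zero, 1.0, rng_range)
        Xn = (X - X.min(axis=0)) / safe_range
        Xn[:, zero] = 0.0

        prior = {c: cnt / m for c, cnt in zip(classes, counts)}
        # full pairwise Manhattan distances on normalized features
        dist = np.abs(Xn[:, None, :] - Xn[None, :, :]).sum(axis=2)
        np.fill_diagonal(dist, np.inf)

        w = np.zeros(n_feat)
        k = self.k_neighbors
        for i in range(m):
            ci = y[i]
            hits = np.where(y == ci)[0]
            hits = hits[hits != i]
            if len(hits):
                nh = hits[np.argsort(dist[i, hits], kind="stable")[:k]]
                diffs = np.abs(Xn[nh] - Xn[i]).sum(axis=0)
                w -= diffs / (m * k)
            for c in classes:
                if c == ci:
                    continue
                miss = np.where(y == c)[0]
                if not len(miss):
                    continue
                nm = miss[np.argsort(dist[i, miss], kind="stable")[:k]]
                diffs = np.abs(Xn[nm] - Xn[i]).sum(axis=0)
                w += (prior[c] / (1.0 - prior[ci])) * diffs / (m * k)
        w[zero] = 0.0
        self.weights_ = w
        order = np.lexsort((np.arange(n_feat), -w))
        self.ranking_ = order
        self.top_indices_ = np.sort(order[: min(self.n_keep, n_feat)])
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float)[:, self.top_indices_]


def grid_search_train(
    X: np.ndarray,
    y: np.ndarray,
    c_grid=DEFAULT_C_GRID,
    gamma_grid=DEFAULT_GAMMA_GRID,
    inner_folds: int = 5,
    seed: int = 0,
) -> tuple[SVC, tuple[float, float]]:
    """Fit an RBF C-SVC with (C, gamma) from an inner stratified grid search.

    Ties in inner-CV accuracy resolve to the smallest C, then the smallest
    gamma (guaranteed by ascending grids and first-maximum selection).
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise DegenerateDataError("training set contains a single class")
    inner = StratifiedKFold(inner_folds, shuffle=True, random_state=seed)
    gs = GridSearchCV(
        SVC(kernel="rbf"),
        {"C": sorted(c_grid), "gamma": sorted(gamma_grid)},
        cv=inner,
        n_jobs=None,
    )
    gs.fit(np.asarray(X, dtype=float), y)
    return gs.best_estimator_, (gs.best_params_["C"], gs.best_params_["gamma"])


class IntentionDecoder(BaseEstimator, ClassifierMixin):
    """z-score -> Relief-F -> grid-searched RBF-SVC, all fit on training data.

    Fitted attributes: ``scaler_``, ``relieff_``, ``svm_``, ``best_params_``
    (chosen (C, gamma)), ``selected_features_`` (column indices kept).
    """

    def __init__(
        self,
        n_keep: int = 60,
        k_neighbors: int = 10,
        c_grid=DEFAULT_C_GRID,
        gamma_grid=DEFAULT_GAMMA_GRID,
        inner_folds: int = 5,
        seed: int = 0,
    ):
        self.n_keep = n_keep
        self.k_neighbors = k_neighbors
        self.c_grid = c_grid
        self.gamma_grid = gamma_grid
        self.inner_folds = inner_folds
        self.seed = seed

    def fit(self, X: np.ndarray, y: np.ndarray) -> "IntentionDecoder":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.scaler_ = StandardScaler().fit(X)
        Xs = self.scaler_.transform(X)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.relieff_ = ReliefF(self.n_keep, self.k_neighbors).fit(Xs, y)
        Xr = self.relieff_.transform(Xs)
        self.svm_, self.best_params_ = grid_search_train(
            Xr, y, self.c_grid, self.gamma_grid, self.inner_folds, self.seed
        )
        self.selected_features_ = self.relieff_.top_indices_.copy()
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = self.scaler_.transform(np.asarray(X, dtype=float))
        return self.svm_.predict(self.relieff_.transform(Xs))


@dataclass
class CVResult:
    """Repeated stratified cross-validation record."""

    accuracies: np.ndarray  # (n_reps, n_folds)
    confusion: np.ndarray  # (n_classes, n_classes) counts, rows = true
    classes: list[str]
    selected_features: list[np.ndarray] = field(default_factory=list)
    chosen_params: list[tuple[float, float]] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def confusion_accuracy(self) -> float:
        return float(np.trace(self.confusion) / self.confusion.sum())


def repeated_cv(
    features: np.ndarray,
    labels: np.ndarray,
    n_reps: int = 10,
    n_folds: int = 10,
    decoder: IntentionDecoder | None = None,
    seed: int = 0,
) -> CVResult:
    """10x10-fold (by default) stratified CV of the full decoding pipeline.

    All fitting — scaling, Relief-F, inner grid search — happens inside each
    training fold; test folds only ever see ``predict``.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes = sorted(np.unique(y).tolist())
    class_to_idx = {c: i for i, c in enumerate(classes)}
    proto = decoder if decoder is not None else IntentionDecoder()

    splitter = RepeatedStratifiedKFold(
        n_splits=n_folds, n_repeats=n_reps, random_state=seed
    )
    accs = np.empty(n_reps * n_folds)
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    selected: list[np.ndarray] = []
    params: list[tuple[float, float]] = []
    for f, (tr, te) in enumerate(splitter.split(X, y)):
        if len(np.unique(y[tr])) < len(classes):
            raise DegenerateDataError(
                f"fold {f}: training split is missing a class"
            )
        dec = clone(proto)
        dec.set_params(seed=proto.seed + f)
        dec.fit(X[tr], y[tr])
        pred = dec.predict(X[te])
        accs[f] = float(np.mean(pred == y[te]))
        for t, p in zip(y[te], pred):
            confusion[class_to_idx[t], class_to_idx[p]] += 1
        selected.append(dec.selected_features_)
        params.append(dec.best_params_)
    return CVResult(
        accuracies=accs.reshape(n_reps, n_folds),
        confusion=confusion,
        classes=[str(c) for c in classes],
        selected_features=selected,
        chosen_params=params,
    )


@dataclass
class ModalityComparison:
    f_statistic: float
    p: float
    df: tuple[int, int]
    pairwise_p: dict[tuple[str, str], float]  # Bonferroni-corrected
    modalities: list[str]


def modality_comparison(
    accuracies: np.ndarray, modalities: list[str]
) -> ModalityComparison:
    """One-way ANOVA over modality columns of a subjects x modalities table,
    with Bonferroni-corrected pairwise t-tests."""
    acc = np.asarray(accuracies, dtype=float)
    if acc.ndim != 2 or acc.shape[1] != len(modalities):
        raise ValueError("accuracies must be subjects x modalities")
    if acc.shape[0] < 2:
        raise DegenerateDataError("need at least 2 subjects")
    cols = [acc[:, j] for j in range(acc.shape[1])]
    if all(np.allclose(c.var(), 0) for c in cols):
        raise DegenerateDataError("no variance in any modality column")
    f, p = stats.f_oneway(*cols)
    pairs = list(combinations(range(len(modalities)), 2))
    raw = np.array([stats.ttest_ind(cols[a], cols[b]).pvalue for a, b in pairs])
    corr = bonferroni(raw, len(pairs))
    return ModalityComparison(
        f_statistic=float(f),
        p=float(p),
        df=(len(modalities) - 1, acc.size - len(modalities)),
        pairwise_p={
            (modalities[a], modalities[b]): float(c)
            for (a, b), c in zip(pairs, corr)
        },
        modalities=list(modalities),
    )
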