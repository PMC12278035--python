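"""Max-relevance-max-distance (MRMD) feature ranking and subset selection.

Each feature column is scored by two terms:

* **relevance** MR_i — the absolute Pearson correlation between the column
  and the binary class vector (a strong negative correlation is as useful
  for classification as a strong positive one);
* **distance** MD_i = ED_i + COS_i + TC_i — the column's mean separation
  from every other column, measured on min-max-normalised columns by
  Euclidean distance, cosine distance (1 - cosine similarity) and Tanimoto
  distance (1 - a·b / (|a|² + |b|² - a·b)).  A column far from the others
  carries little redundant information.

MR and MD have incomparable scales, so each is min-max scaled to [0, 1]
across features before being summed into the combined MRMD score; features
are ranked by descending score with ties broken by lower column index.

Subset selection is a forward wrapper over the ranked list: prefixes of
increasing size k are evaluated by stratified cross-validated accuracy and
the smallest k attaining the maximum is chosen.

:class:`MRMDSelector` wraps ranking + selection as a scikit-learn feature
selector usable inside pipelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist
from sklearn.base import BaseEstimator, clone
from sklearn.feature_selection import SelectorMixin
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.utils.validation import check_X_y, check_is_fitted


@dataclass(frozen=True)
class FeatureScore:
    """MRMD ranking record for one feature column."""

    index: int
    name: str
    relevance: float  # MR, |Pearson r| with the class vector
    distance: float   # MD, mean ED + cosine + Tanimoto separation
    score: float      # scaled MR + scaled MD
    rank: int         # 1-based


def _check_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("labels must contain both classes")
    return y.astype(float)


def max_relevance(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """MR_i = |Pearson correlation of column i with the class vector|.

    Zero-variance columns get MR = 0 with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = _check_labels(y)
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    ss_x = (xc ** 2).sum(axis=0)
    ss_y = (yc ** 2).sum()
    zero = ss_x == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-variance feature column(s) assigned "
            "relevance 0", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.abs(xc.T @ yc) / np.sqrt(ss_x * ss_y)
    r[zero] = 0.0
    return r


def max_distance(X: np.ndarray) -> np.ndarray:
    """MD_i = mean Euclidean + cosine + Tanimoto distance to other columns.

    Columns are min-max normalised to [0, 1] first.  Pairs involving an
    all-zero normalised column have undefined cosine/Tanimoto similarity;
    those pairs contribute distance 0 (warned).  Requires >= 2 columns.
    """
    X = np.asarray(X, dtype=float)
    m = X.shape[1]
    if m < 2:
        raise ValueError("max_distance needs at least 2 feature columns")
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = np.where(span > 0, (X - lo) / np.where(span > 0, span, 1.0), 0.0)

    ed = squareform(pdist(Z.T, metric="euclidean"))

    norms_sq = (Z ** 2).sum(axis=0)
    zero = norms_sq == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} all-zero normalised column(s): cosine and "
            "Tanimoto terms set to 0 for their pairs", stacklevel=2)
    G = Z.T @ Z
    denom_cos = np.sqrt(np.outer(norms_sq, norms_sq))
    denom_tc = norms_sq[:, None] + norms_sq[None, :] - G
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_sim = np.where(denom_cos > 0, G / np.where(denom_cos > 0, denom_cos, 1.0), 1.0)
        tc_sim = np.where(denom_tc > 0, G / np.where(denom_tc > 0, denom_tc, 1.0), 1.0)
    # undefined similarities (zero columns) -> similarity 1 -> distance 0
    cos = 1.0 - cos_sim
    tc = 1.0 - tc_sim
    np.fill_diagonal(ed, 0.0)
    np.fill_diagonal(cos, 0.0)
    np.fill_diagonal(tc, 0.0)
    return (ed.sum(axis=1) + cos.sum(axis=1) + tc.sum(axis=1)) / (m - 1)


def _scale01(v: np.ndarray) -> np.ndarray:
    span = v.max() - v.min()
    if span == 0:
        return np.zeros_like(v)
    return (v - v.min()) / span


def rank_features(X: np.ndarray, y: np.ndarray,
                  names: list[str] | None = None) -> list[FeatureScore]:
    """Rank all columns by the combined MRMD score.

    MR and MD are each min-max scaled to [0, 1] across features and summed;
    ties are broken by lower column index.  For a single column MD is
    defined as 0.  Returns one :class:`FeatureScore` per column, in rank
    order.
    """
    X = np.asarray(X, dtype=float)
    m = X.shape[1]
    if names is None:
        names = [f"f{i}" for i in range(m)]
    if len(names) != m:
        raise ValueError("names length must match the number of columns")
    mr = max_relevance(X, y)
    md = max_distance(X) if m >= 2 else np.zeros(1)
    score = _scale01(mr) + _scale01(md)
    order = np.lexsort((np.arange(m), -score))
    return [
        FeatureScore(index=int(i), name=names[i], relevance=float(mr[i]),
                     distance=float(md[i]), score=float(score[i]), rank=r + 1)
        for r, i in enumerate(order)
    ]


def default_k_grid(m: int, dense_upto: int = 10, n_sparse: int = 15) -> list[int]:
    """Prefix sizes evaluated by the forward wrapper.

    Every k up to ``dense_upto`` plus ~``n_sparse`` geometrically spaced
    sizes up to m (all of 1..m when m is small).
    """
    if m <= dense_upto + n_sparse:
        return list(range(1, m + 1))
    dense = list(range(1, dense_upto + 1))
    sparse = np.unique(np.geomspace(dense_upto + 1, m, n_sparse).round().astype(int))
    return sorted(set(dense) | set(int(k) for k in sparse))


def select_subset(X: np.ndarray, y: np.ndarray, names: list[str] | None = None,
                  estimator=None, cv: int = 10, seed: int = 1,
                  k_grid: list[int] | None = None):
    """Choose a compact feature subset by forward evaluation of MRMD prefixes.

    Each prefix size k in the grid is scored by stratified ``cv``-fold
    cross-validated accuracy of ``estimator`` (default: a lightly
    regularised logistic regression) on the top-k ranked columns; the
    smallest k attaining the maximum accuracy wins.

    Returns ``(chosen_indices, trace)`` where ``chosen_indices`` are
    original column indices in rank order and ``trace`` is a list of
    ``{"k": ..., "accuracy": ...}`` records.
    """
    X = np.asarray(X, dtype=float)
    ranking = rank_features(X, y, names)
    ranked_idx = [fs.index for fs in ranking]
    if estimator is None:
        estimator = LogisticRegression(C=1e4, max_iter=1000)
    if k_grid is None:
        k_grid = default_k_grid(X.shape[1])
    splitter = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
    trace = []
    for k in k_grid:
        acc = cross_val_score(clone(estimator), X[:, ranked_idx[:k]], y,
                              cv=splitter, scoring="accuracy").mean()
        trace.append({"k": int(k), "accuracy": float(acc)})
    best_acc = max(t["accuracy"] for t in trace)
    best_k = min(t["k"] for t in trace if t["accuracy"] >= best_acc - 1e-12)
    return ranked_idx[:best_k], trace


class MRMDSelector(SelectorMixin, BaseEstimator):
    """Scikit-learn feature selector based on MRMD ranking.

    Parameters
    ----------
    n_features : int or "auto"
        Fixed subset size, or ``"auto"`` to pick the smallest prefix of the
        ranked list maximising cross-validated accuracy.
    estimator : classifier, optional
        Wrapper evaluator for ``"auto"`` mode (default logistic regression).
    cv : int
        Stratified fold count for the wrapper (default 10).
    random_state : int
        Seed for the fold shuffling.
    k_grid : list of int, optional
        Prefix sizes to evaluate in ``"auto"`` mode.

    Attributes
    ----------
    ranking_ : list of FeatureScore, in rank order
    support_ : boolean mask of selected columns
    selected_indices_ : chosen original column indices, rank order
    selection_trace_ : per-k accuracy trace ("auto" mode only)
    """

    def __init__(self, n_features="auto", estimator=None, cv: int = 10,
                 random_state: int = 1, k_grid=None):
        self.n_features = n_features
        self.estimator = estimator
        self.cv = cv
        self.random_state = random_state
        self.k_grid = k_grid

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.n_features_in_ = X.shape[1]
        self.ranking_ = rank_features(X, y)
        if self.n_features == "auto":
            chosen, trace = select_subset(
                X, y, estimator=self.estimator, cv=self.cv,
                seed=self.random_state, k_grid=self.k_grid)
            self.selection_trace_ = trace
        else:
            k = int(self.n_features)
            if not 1 <= k <= X.shape[1]:
                raise ValueError(f"n_features must be in 1..{X.shape[1]}")
            chosen = [fs.index for fs in self.ranking_[:k]]
        self.selected_indices_ = chosen
        mask = np.zeros(X.shape[1], dtype=bool)
        mask[chosen] = True
        self.support_ = mask
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_
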