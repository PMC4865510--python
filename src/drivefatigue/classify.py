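"""FLDA classification, time-ordered sliding splits, fusion, and testing.

Per-trial features of each modality are classified with Fisher's linear
discriminant (FLDA).  Because trials are a time series, train/test splits
respect temporal order: 70% contiguous trials train, 30% test, the last
six trials (one minute) of each block dropped so no train trial lies
within one minute of a test trial, and the whole scheme slides by one
minute for 30 repetitions.

Modality fusion follows classifier stacking: each modality's FLDA output
score is treated as an input feature of a second-level FLDA.  First-level
scores on the training block are produced out-of-fold so the second-level
classifier never sees scores from a model trained on the same trials.

Condition comparisons across the small subject sample use the exact
(full-enumeration) Wilcoxon signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted


class FisherLDA(BaseEstimator, ClassifierMixin):
    """Two-class Fisher linear discriminant with midpoint boundary.

    The weight vector is ``w = (S_pooled + lam*I)^-1 (mu_1 - mu_0)`` with a
    small ridge ``lam = shrinkage * trace(S)/d`` for numerical stability;
    the bias places the decision boundary at the projected midpoint of the
    class means.  Scores ``w.x + b`` are positive for class 1; exact zeros
    break to class 0 (the well-rested condition in this package's
    encoding).

    Parameters
    ----------
    shrinkage : float
        Relative ridge added to the pooled covariance diagonal.
    """

    def __init__(self, shrinkage: float = 1e-3):
        self.shrinkage = shrinkage

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError(f"FisherLDA is two-class; got classes {classes}")
        X0, X1 = X[y == classes[0]], X[y == classes[1]]
        mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
        n0, n1 = len(X0), len(X1)
        d = X.shape[1]
        cov = ((X0 - mu0).T @ (X0 - mu0) + (X1 - mu1).T @ (X1 - mu1)) / max(n0 + n1 - 2, 1)
        lam = self.shrinkage * np.trace(cov) / d if np.trace(cov) > 0 else self.shrinkage
        w = np.linalg.solve(cov + lam * np.eye(d), mu1 - mu0)
        self.classes_ = classes
        self.coef_ = w
        self.intercept_ = -float(w @ (mu0 + mu1) / 2.0)
        self.means_ = np.vstack([mu0, mu1])
        self.covariance_ = cov
        self.n_features_in_ = d
        return self

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; model was fitted with {self.n_features_in_}")
        return X @ self.coef_ + self.intercept_

    def predict(self, X):
        scores = self.decision_function(X)
        return np.where(scores > 0, self.classes_[1], self.classes_[0])


@dataclass(frozen=True)
class SplitScheme:
    """Per-repetition train/test trial indices (shared across conditions)."""

    train: tuple[np.ndarray, ...]
    test: tuple[np.ndarray, ...]

    @property
    def n_reps(self) -> int:
        return len(self.train)


def make_splits(n_trials: int = 180, train_frac: float = 0.7, buffer_trials: int = 6,
                n_reps: int = 30, shift_trials: int = 6, circular: bool = True) -> SplitScheme:
    """Time-ordered 70/30 splits with a one-minute buffer, slid per repetition.

    Repetition ``r`` rotates the trial order by ``r * shift_trials`` (when
    ``circular``), takes the first 70% as the training block and the rest
    as the test block, then drops the last ``buffer_trials`` of each block.
    Defaults reproduce the 180 -> 126/54 -> 120/48 bookkeeping of a 30-min
    session.  With ``circular=False`` repetitions that would wrap are
    instead truncated sliding windows and fewer than ``n_reps`` may fit.
    """
    block = train_frac * n_trials
    if abs(block - round(block)) > 1e-9:
        raise ValueError("train_frac * n_trials must be an integer")
    block = int(round(block))
    n_test_block = n_trials - block
    if block - buffer_trials < 1 or n_test_block - buffer_trials < 1:
        raise ValueError("buffer leaves no trials in a block")
    trains, tests = [], []
    for r in range(n_reps):
        offset = r * shift_trials
        if circular:
            order = (np.arange(n_trials) + offset) % n_trials
        else:
            if offset + n_trials > n_trials and offset > 0:
                break
            order = np.arange(n_trials)
        trains.append(order[: block - buffer_trials])
        tests.append(order[block: n_trials - buffer_trials])
    return SplitScheme(train=tuple(trains), test=tuple(tests))


def _check_features(X: np.ndarray, n_trials: int) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != n_trials:
        raise ValueError("feature rows must equal the trial count")
    return X


def evaluate_modality(X_well: np.ndarray, X_sleep: np.ndarray,
                      splits: SplitScheme, shrinkage: float = 1e-3) -> np.ndarray:
    """Per-repetition test accuracy of a single-modality FLDA.

    The same trial-index split is applied within each condition; class 0
    is well-rested, class 1 sleep-deprived.
    """
    n_trials = np.asarray(X_well).shape[0]
    Xw = _check_features(X_well, n_trials)
    Xs = _check_features(X_sleep, n_trials)
    acc = np.empty(splits.n_reps)
    for r, (tr, te) in enumerate(zip(splits.train, splits.test)):
        Xtr = np.vstack([Xw[tr], Xs[tr]])
        ytr = np.r_[np.zeros(len(tr), int), np.ones(len(tr), int)]
        Xte = np.vstack([Xw[te], Xs[te]])
        yte = np.r_[np.zeros(len(te), int), np.ones(len(te), int)]
        model = FisherLDA(shrinkage=shrinkage).fit(Xtr, ytr)
        acc[r] = float(np.mean(model.predict(Xte) == yte))
    return acc


def _contiguous_folds(n: int, n_folds: int) -> list[np.ndarray]:
    edges = np.linspace(0, n, n_folds + 1).round().astype(int)
    return [np.arange(edges[i], edges[i + 1]) for i in range(n_folds)]


class StackedFLDA(BaseEstimator, ClassifierMixin):
    """Second-level FLDA over first-level per-modality FLDA scores.

    ``feature_groups`` lists the column indices of each modality within
    the stacked feature matrix.  During ``fit``, first-level scores for
    the second-level training set are produced out-of-fold with a
    contiguous ``n_folds``-fold split (trials are a time series, so folds
    are blocks, not random subsets); the first-level models exposed for
    prediction are refit on the full training data.
    """

    def __init__(self, feature_groups=None, n_folds: int = 5, shrinkage: float = 1e-3):
        self.feature_groups = feature_groups
        self.n_folds = n_folds
        self.shrinkage = shrinkage

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        groups = self.feature_groups
        if groups is None or len(groups) < 2:
            raise ValueError("stacking needs at least two modality feature groups")
        n = len(y)
        folds = _contiguous_folds(n, self.n_folds)
        meta = np.empty((n, len(groups)))
        for m, cols in enumerate(groups):
            Xm = X[:, np.asarray(cols, int)]
            for fold in folds:
                mask = np.ones(n, bool)
                mask[fold] = False
                if np.unique(y[mask]).size < 2:
                    raise ValueError("a stacking fold lost one class entirely")
                lvl1 = FisherLDA(shrinkage=self.shrinkage).fit(Xm[mask], y[mask])
                meta[fold, m] = lvl1.decision_function(Xm[fold])
        self.first_level_ = [
            FisherLDA(shrinkage=self.shrinkage).fit(X[:, np.asarray(cols, int)], y)
            for cols in groups
        ]
        self.second_level_ = FisherLDA(shrinkage=self.shrinkage).fit(meta, y)
        self.classes_ = self.second_level_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def _meta_features(self, X):
        X = np.asarray(X, dtype=float)
        return np.column_stack([
            model.decision_function(X[:, np.asarray(cols, int)])
            for model, cols in zip(self.first_level_, self.feature_groups)
        ])

    def decision_function(self, X):
        check_is_fitted(self, "second_level_")
        return self.second_level_.decision_function(self._meta_features(X))

    def predict(self, X):
        check_is_fitted(self, "second_level_")
        return self.second_level_.predict(self._meta_features(X))


def fuse_classifiers(features_well: list[np.ndarray], features_sleep: list[np.ndarray],
                     splits: SplitScheme, n_folds: int = 5,
                     shrinkage: float = 1e-3) -> np.ndarray:
    """Per-repetition accuracy of the stacked multi-modality classifier."""
    if len(features_well) < 2 or len(features_well) != len(features_sleep):
        raise ValueError("need matching feature lists for at least two modalities")
    n_trials = np.asarray(features_well[0]).shape[0]
    Xw_list = [_check_features(f, n_trials) for f in features_well]
    Xs_list = [_check_features(f, n_trials) for f in features_sleep]
    groups, start = [], 0
    for f in Xw_list:
        groups.append(np.arange(start, start + f.shape[1]))
        start += f.shape[1]
    Xw = np.hstack(Xw_list)
    Xs = np.hstack(Xs_list)
    acc = np.empty(splits.n_reps)
    for r, (tr, te) in enumerate(zip(splits.train, splits.test)):
        Xtr = np.vstack([Xw[tr], Xs[tr]])
        ytr = np.r_[np.zeros(len(tr), int), np.ones(len(tr), int)]
        Xte = np.vstack([Xw[te], Xs[te]])
        yte = np.r_[np.zeros(len(te), int), np.ones(len(te), int)]
        model = StackedFLDA(feature_groups=groups, n_folds=n_folds,
                            shrinkage=shrinkage).fit(Xtr, ytr)
        acc[r] = float(np.mean(model.predict(Xte) == yte))
    return acc


def wilcoxon_signed_rank_exact(a, b) -> tuple[float, float]:
    """Exact two-sided Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped (the standard Wilcoxon convention).
    Ranks of |d| use average ranks on ties; the null distribution of the
    positive-rank sum is computed exactly over all 2^n sign assignments
    via dynamic programming.  Returns (W+, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero")
    if n > 25:
        raise ValueError("exact enumeration limited to n <= 25")
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    # DP over doubled ranks (average ranks may be half-integral)
    r2 = np.round(2 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        counts[r:] = counts[r:] + counts[:-r or None]
    counts /= counts.sum()
    w2 = int(round(2 * w_plus))
    p_low = counts[: w2 + 1].sum()
    p_high = counts[w2:].sum()
    p = min(1.0, 2.0 * min(p_low, p_high))
    return w_plus, float(p)
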