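"""Nearest shrunken centroid classification (the PAM-style classifier).

Per feature i and class k the standardized centroid difference is

    d_ik = (xbar_ik - xbar_i) / (m_k (s_i + s0)),   m_k^2 = 1/n_k - 1/n,

soft-thresholded by Delta: ``d'_ik = sign(d_ik) max(0, |d_ik| - Delta)``.
Features with all ``d'_ik = 0`` drop out of the classifier, giving a
sparse signature whose size is nonincreasing in Delta.  A sample x is
assigned to the class minimizing the discriminant

    delta_k(x) = sum_i (x_i - xbar'_ik)^2 / (s_i + s0)^2 - 2 log pi_k

with shrunken centroids ``xbar'_ik = xbar_i + m_k (s_i + s0) d'_ik``.

``NearestShrunkenCentroid`` follows the scikit-learn estimator API
(samples x features); the module-level functions operate on the
pipeline's probes x samples :class:`ExpressionMatrix`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .containers import ExpressionMatrix


class NearestShrunkenCentroid(BaseEstimator, ClassifierMixin):
    """Nearest shrunken centroid classifier.

    Parameters
    ----------
    delta : float, default=0.0
        Soft-threshold applied to the standardized centroid differences.
        ``delta=0`` reduces to a plain (standardized) nearest-centroid
        classifier.
    s0 : float or "median", default="median"
        Fudge factor added to per-feature pooled standard deviations;
        "median" uses the median of ``s_i``.
    priors : "empirical" or array-like, default="empirical"
        Class prior probabilities.
    """

    def __init__(self, delta: float = 0.0, s0="median", priors="empirical"):
        self.delta = delta
        self.s0 = s0
        self.priors = priors

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        classes, y_idx = np.unique(y, return_inverse=True)
        if len(classes) < 2:
            raise ValueError("need >= 2 classes")
        n, p = X.shape
        counts = np.bincount(y_idx)
        if (counts < 2).any():
            bad = classes[np.argmin(counts)]
            raise ValueError(f"class {bad!r} has fewer than 2 samples")
        self.classes_ = classes
        self.class_counts_ = counts
        self.overall_centroid_ = X.mean(axis=0)
        cent = np.vstack([X[y_idx == k].mean(axis=0) for k in range(len(classes))])
        self.class_centroids_ = cent
        ss = np.zeros(p)
        for k in range(len(classes)):
            ss += ((X[y_idx == k] - cent[k]) ** 2).sum(axis=0)
        self.s_ = np.sqrt(ss / (n - len(classes)))
        self.s0_ = float(np.median(self.s_)) if self.s0 == "median" else float(self.s0)
        self.mk_ = np.sqrt(1.0 / counts - 1.0 / n)
        denom = self.mk_[:, None] * (self.s_ + self.s0_)[None, :]
        self.dik_ = (cent - self.overall_centroid_[None, :]) / denom
        self.shrunken_dik_ = soft_threshold(self.dik_, self.delta)
        self.shrunken_centroids_ = (
            self.overall_centroid_[None, :] + denom * self.shrunken_dik_
        )
        if isinstance(self.priors, str) and self.priors == "empirical":
            self.priors_ = counts / n
        else:
            pr = np.asarray(self.priors, dtype=float)
            if len(pr) != len(classes) or not np.isclose(pr.sum(), 1.0):
                raise ValueError("priors must have one entry per class and sum to 1")
            self.priors_ = pr
        return self

    def decision_scores(self, X) -> np.ndarray:
        """Discriminant ``delta_k(x)`` per sample and class (lower wins)."""
        check_is_fitted(self, "shrunken_centroids_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.shrunken_centroids_.shape[1]:
            raise ValueError(
                f"X has {X.shape[1]} features; model was fitted with "
                f"{self.shrunken_centroids_.shape[1]}"
            )
        w = 1.0 / (self.s_ + self.s0_) ** 2
        scores = np.empty((X.shape[0], len(self.classes_)))
        for k in range(len(self.classes_)):
            diff = X - self.shrunken_centroids_[k][None, :]
            scores[:, k] = (diff * diff * w[None, :]).sum(axis=1) - 2.0 * np.log(
                self.priors_[k]
            )
        return scores

    def predict(self, X):
        labels, _, _ = self.predict_with_scores(X)
        return labels

    def predict_with_scores(self, X):
        """(labels, discriminant scores, tie flags); ties resolve to the
        lexicographically first class (classes_ is sorted)."""
        scores = self.decision_scores(X)
        best = scores.argmin(axis=1)
        ties = (np.isclose(scores, scores.min(axis=1, keepdims=True))).sum(axis=1) > 1
        return self.classes_[best], scores, ties

    @property
    def signature_mask_(self) -> np.ndarray:
        """Boolean mask of features with any nonzero shrunken difference."""
        check_is_fitted(self, "shrunken_dik_")
        return (self.shrunken_dik_ != 0).any(axis=0)

    def with_delta(self, delta: float) -> "NearestShrunkenCentroid":
        """Re-threshold a fitted model at a new Delta without refitting."""
        check_is_fitted(self, "dik_")
        clone = NearestShrunkenCentroid(delta=delta, s0=self.s0, priors=self.priors)
        for attr in (
            "classes_",
            "class_counts_",
            "overall_centroid_",
            "class_centroids_",
            "s_",
            "s0_",
            "mk_",
            "dik_",
            "priors_",
        ):
            setattr(clone, attr, getattr(self, attr))
        clone.shrunken_dik_ = soft_threshold(clone.dik_, delta)
        denom = clone.mk_[:, None] * (clone.s_ + clone.s0_)[None, :]
        clone.shrunken_centroids_ = (
            clone.overall_centroid_[None, :] + denom * clone.shrunken_dik_
        )
        return clone


def soft_threshold(d: np.ndarray, delta: float) -> np.ndarray:
    return np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)


# ---------------------------------------------------------------------------
# ExpressionMatrix front-end


@dataclass
class ClassifierReport:
    """Cross-validation report: per-Delta class errors, the chosen Delta
    (largest within one standard error of the minimum overall error),
    the signature at that Delta, and per-sample CV predictions."""

    cv_errors: pd.DataFrame  # delta, overall_error, se, error_<class>...
    chosen_delta: float
    model: NearestShrunkenCentroid
    signature: pd.DataFrame
    predictions: pd.DataFrame  # sample_id, true, predicted (cross-validated)


def _matrix_to_xy(m: ExpressionMatrix, labels: pd.Series):
    samples = [s for s in m.sample_ids if s in labels.index and pd.notna(labels[s])]
    X = m.values[samples].to_numpy(dtype=float).T
    if np.isnan(X).any():
        raise ValueError("classifier input must have no masked cells; filter first")
    y = labels[samples].to_numpy()
    return X, y, samples


def train_nsc(
    m: ExpressionMatrix, labels: pd.Series, delta: float = 0.0, s0="median"
) -> NearestShrunkenCentroid:
    X, y, _ = _matrix_to_xy(m, labels)
    return NearestShrunkenCentroid(delta=delta, s0=s0).fit(X, y)


def predict_nsc(model: NearestShrunkenCentroid, m: ExpressionMatrix) -> pd.DataFrame:
    X = m.values.to_numpy(dtype=float).T
    labels, scores, ties = model.predict_with_scores(X)
    out = pd.DataFrame(
        scores, index=m.sample_ids, columns=[f"score_{c}" for c in model.classes_]
    )
    out.insert(0, "predicted", labels)
    out["tie"] = ties
    out.index.name = "sample_id"
    return out


def extract_signature(
    model: NearestShrunkenCentroid, probe_ids: list[str]
) -> pd.DataFrame:
    """Probes with nonzero shrunken difference, ordered by max_k |d'_ik|
    descending."""
    check_is_fitted(model, "shrunken_dik_")
    mask = model.signature_mask_
    rows = pd.DataFrame(
        model.shrunken_dik_.T,
        index=probe_ids,
        columns=[f"d_{c}" for c in model.classes_],
    )
    rows = rows[mask]
    rows["max_abs_d"] = np.abs(rows.to_numpy()).max(axis=1)
    rows = rows.sort_values("max_abs_d", ascending=False, kind="mergesort")
    rows.index.name = "probe_id"
    return rows


def cross_validate_nsc(
    m: ExpressionMatrix,
    labels: pd.Series,
    delta_grid=None,
    k_folds: int = 5,
    seed: int = 0,
    s0="median",
) -> ClassifierReport:
    """Stratified k-fold cross-validation over a Delta grid.

    Per Delta, per-class error = misclassified / class size over the
    pooled out-of-fold predictions.  The chosen Delta is the largest
    whose overall error is within one standard error (across folds) of
    the minimum; the final model is refitted on all samples at that
    Delta.
    """
    if delta_grid is None:
        delta_grid = np.round(np.arange(0.0, 4.01, 0.1), 10)
    delta_grid = np.asarray(sorted(delta_grid), dtype=float)
    X, y, samples = _matrix_to_xy(m, labels)
    classes, y_idx = np.unique(y, return_inverse=True)
    min_class = np.bincount(y_idx).min()
    if k_folds > min_class:
        raise ValueError(
            f"k_folds={k_folds} exceeds the smallest class size {min_class}; "
            "use leave-one-out (k_folds = min class size)"
        )
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    n_d = len(delta_grid)
    preds = np.empty((n_d, len(y)), dtype=object)
    fold_errors = np.zeros((n_d, k_folds))
    for f, (tr, te) in enumerate(skf.split(X, y)):
        base = NearestShrunkenCentroid(delta=0.0, s0=s0).fit(X[tr], y[tr])
        for di, delta in enumerate(delta_grid):
            mdl = base.with_delta(delta)
            yh = mdl.predict(X[te])
            preds[di, te] = yh
            fold_errors[di, f] = np.mean(yh != y[te])
    overall = np.array([(preds[di] != y).mean() for di in range(n_d)])
    se = fold_errors.std(axis=1, ddof=1) / np.sqrt(k_folds)
    best = overall.argmin()
    threshold = overall[best] + se[best]
    chosen = float(delta_grid[np.where(overall <= threshold)[0].max()])
    err_cols = {"delta": delta_grid, "overall_error": overall, "se": se}
    for c in classes:
        sel = y == c
        err_cols[f"error_{c}"] = [
            (preds[di, sel] != y[sel]).mean() for di in range(n_d)
        ]
    final = train_nsc(m, labels, delta=chosen, s0=s0)
    report = ClassifierReport(
        cv_errors=pd.DataFrame(err_cols),
        chosen_delta=chosen,
        model=final,
        signature=extract_signature(final, m.probe_ids),
        predictions=pd.DataFrame(
            {
                "sample_id": samples,
                "true": y,
                "predicted": preds[int(np.where(delta_grid == chosen)[0][0])],
            }
        ),
    )
    return report
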