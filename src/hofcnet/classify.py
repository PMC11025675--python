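"""Diagnostic classification from connectivity-derived features.

Per subject, a length-P feature vector of Onnela weighted local clustering
coefficients is computed from the (unthresholded, positive-weight)
connectivity matrix.  Classification is L1-regularised feature selection
(LASSO, penalty chosen by inner 5-fold cross-validation) followed by a
linear support vector machine (C = 1), evaluated by nested leave-one-out
cross-validation: scaling, selection and fitting are all re-done inside
each training fold so no information from the held-out subject leaks in.
Patient is the positive class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.linear_model import LassoCV
from sklearn.model_selection import KFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .connectivity import ConnectivityMatrix

logger = logging.getLogger(__name__)


@dataclass
class ClassifierConfig:
    svm_c: float = 1.0
    n_alphas: int = 50
    alpha_path_span: float = 1e-2   # ratio alpha_min / alpha_max on the path
    inner_folds: int = 5
    seed: int = 0


@dataclass
class FoldRecord:
    index: int
    true_label: int
    predicted: int
    decision_value: float
    selected_features: list


@dataclass
class ClassificationResult:
    folds: list
    tp: int
    fn: int
    tn: int
    fp: int
    auc: float
    acc: float
    sen: float
    spe: float
    f_score: float | None


def clustering_features(m: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    """Onnela weighted local clustering coefficient per node.

    Negative weights are zeroed, weights are normalised by the matrix
    maximum, and c_i = sum_{j,h} (w_ij w_ih w_jh)^(1/3) / (k_i (k_i - 1))
    with k_i the count of nonzero weights at node i; nodes with k_i < 2
    have no triangle and score 0.
    """
    w = m.values if isinstance(m, ConnectivityMatrix) else np.asarray(m)
    if np.max(np.abs(w - w.T)) > 1e-10:
        raise ValueError("weight matrix must be symmetric")
    w = np.where(w > 0, w, 0.0)
    np.fill_diagonal(w, 0.0)
    wmax = w.max()
    if wmax == 0:
        logger.warning("all-zero weight matrix; clustering features are 0")
        return np.zeros(w.shape[0])
    w3 = np.cbrt(w / wmax)
    numer = np.diag(w3 @ w3 @ w3)
    k = (w > 0).sum(axis=1)
    denom = k * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, numer / denom, 0.0)
    return c


def roc_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """ROC area via the rank (Mann-Whitney) statistic, ties at half credit."""
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for an ROC AUC")
    ranks = stats.rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def confusion_from_rates(sen_pct: float, spe_pct: float,
                         n_pos: int, n_neg: int) -> tuple[int, int, int, int]:
    """(tp, fn, tn, fp) implied by printed sensitivity/specificity percentages."""
    tp = int(round(sen_pct / 100.0 * n_pos))
    tn = int(round(spe_pct / 100.0 * n_neg))
    return tp, n_pos - tp, tn, n_neg - tn


def metrics_from_confusion(tp: int, fn: int, tn: int, fp: int) -> dict:
    """ACC / SEN / SPE / F-score, all as percentages."""
    total = tp + fn + tn + fp
    acc = 100.0 * (tp + tn) / total
    sen = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
    spe = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
    if tp + fp == 0:
        logger.warning("no positive predictions; precision and F-score undefined")
        f = None
    else:
        prec = tp / (tp + fp)
        rec = tp / (tp + fn)
        f = 100.0 * 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return {"acc": acc, "sen": sen, "spe": spe, "f_score": f}


def _fit_fold(x_train, y_train, config, fold_seed):
    scaler = StandardScaler().fit(x_train)
    xs = scaler.transform(x_train)
    inner = KFold(n_splits=config.inner_folds, shuffle=True,
                  random_state=fold_seed)
    # 50 alphas spanning two decades below the null-model alpha; the Gram
    # precompute makes the coordinate descent cheap at these sample sizes
    lasso = LassoCV(alphas=config.n_alphas, eps=config.alpha_path_span,
                    cv=inner, max_iter=5000, tol=1e-4, precompute=True,
                    random_state=fold_seed)
    import warnings

    from sklearn.exceptions import ConvergenceWarning
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        lasso.fit(xs, y_train.astype(float))
    selected = np.flatnonzero(lasso.coef_ != 0)
    if selected.size == 0:
        logger.info("LASSO selected no features in a fold; falling back to "
                    "all features")
        selected = np.arange(x_train.shape[1])
    svm = SVC(kernel="linear", C=config.svm_c)
    svm.fit(xs[:, selected], y_train)
    return scaler, selected, svm


def nested_loocv_classify(features: np.ndarray, labels,
                          config: ClassifierConfig | None = None
                          ) -> ClassificationResult:
    """Nested leave-one-out evaluation of the LASSO -> linear-SVM pipeline."""
    config = config or ClassifierConfig()
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    n = x.shape[0]
    if min((y == 1).sum(), (y == 0).sum()) < 2:
        raise ValueError("need at least 2 subjects per class")
    folds = []
    for i in range(n):
        train = np.arange(n) != i
        scaler, selected, svm = _fit_fold(x[train], y[train], config,
                                          fold_seed=config.seed)
        xs_test = scaler.transform(x[i:i + 1])[:, selected]
        decision = float(svm.decision_function(xs_test)[0])
        pred = int(svm.predict(xs_test)[0])
        folds.append(FoldRecord(index=i, true_label=int(y[i]), predicted=pred,
                                decision_value=decision,
                                selected_features=selected.tolist()))
    return summarize_folds(folds)


def summarize_folds(folds) -> ClassificationResult:
    y = np.array([f.true_label for f in folds])
    pred = np.array([f.predicted for f in folds])
    dec = np.array([f.decision_value for f in folds])
    tp = int(np.sum((y == 1) & (pred == 1)))
    fn = int(np.sum((y == 1) & (pred == 0)))
    tn = int(np.sum((y == 0) & (pred == 0)))
    fp = int(np.sum((y == 0) & (pred == 1)))
    m = metrics_from_confusion(tp, fn, tn, fp)
    auc = roc_auc(y == 1, dec)
    return ClassificationResult(folds=list(folds), tp=tp, fn=fn, tn=tn, fp=fp,
                                auc=auc, acc=m["acc"], sen=m["sen"],
                                spe=m["spe"], f_score=m["f_score"])
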