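"""kNN and PLSDA classification of RNA ensembles from motif counts.

Both classifiers see only the five per-structure motif counts (bulges,
loops, junctions, helices, bonds).  Evaluation is stratified five-fold
cross-validation; the pooled out-of-fold scores are summarised by ROC AUC
with a 95% bootstrap confidence interval.  PLSDA additionally yields signed
variable importances (fold-averaged regression coefficients on z-scored
features) and unsigned VIP scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler

from .errors import KTooLargeError, SingleClassError
from .sampling import SeedLike, as_rng
from .structure_core import FEATURE_ORDER

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassificationResult:
    method: str
    auc: float
    ci: Tuple[float, float]
    folds: int
    seed: Optional[int]
    params: dict
    importances: Optional[dict] = None  # signed, plsda only
    vip: Optional[dict] = None  # unsigned VIP scores, plsda only
    scores: Optional[np.ndarray] = None  # pooled out-of-fold scores
    labels: Optional[np.ndarray] = None

    def as_dict(self) -> dict:
        d = {"method": self.method, "auc": self.auc, "ci": list(self.ci),
             "folds": self.folds, "seed": self.seed, "params": self.params}
        if self.importances is not None:
            d["importances"] = self.importances
        if self.vip is not None:
            d["vip"] = self.vip
        return d


def _check_two_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise SingleClassError("both classes must be present")


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve (Mann–Whitney convention: ties count 1/2)."""
    y = np.asarray(labels)
    _check_two_classes(y)
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def auc_bootstrap_ci(
    scores: Sequence[float],
    labels: Sequence[int],
    B: int = 1000,
    seed: SeedLike = 0,
) -> Tuple[float, float]:
    """95% percentile bootstrap interval of the AUC over (score, label)
    pair resamples; single-class resamples are redrawn (and logged)."""
    if B < 100:
        raise ValueError(f"need B >= 100 bootstrap replicates, got {B}")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    _check_two_classes(y)
    rng = as_rng(seed)
    n = len(s)
    aucs = np.empty(B)
    n_redrawn = 0
    for b in range(B):
        while True:
            idx = rng.integers(0, n, size=n)
            if len(np.unique(y[idx])) == 2:
                break
            n_redrawn += 1
        aucs[b] = roc_auc_score(y[idx], s[idx])
    if n_redrawn:
        logger.debug("redrew %d single-class bootstrap resamples", n_redrawn)
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return float(lo), float(hi)


def _cv_checks(X: np.ndarray, y: np.ndarray, folds: int) -> None:
    _check_two_classes(y)
    counts = np.bincount(y.astype(int))
    if min(counts[counts > 0]) < 10:
        raise ValueError("need >= 10 records per class for cross-validation")


def _oof_scores(X, y, folds, seed, fit_score):
    """Pooled out-of-fold scores; z-scaling fit on training folds only."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True,
                          random_state=int(seed) % (2**32))
    scores = np.empty(len(y), dtype=float)
    fold_extras = []
    for train, test in skf.split(X, y):
        scaler = StandardScaler().fit(X[train])
        Xtr, Xte = scaler.transform(X[train]), scaler.transform(X[test])
        scores[test], extra = fit_score(Xtr, y[train], Xte)
        fold_extras.append(extra)
    return scores, fold_extras


def knn_cv(
    X: Sequence[Sequence[float]],
    y: Sequence[int],
    k: int = 5,
    folds: int = 5,
    seed: int = 0,
    B: int = 1000,
) -> ClassificationResult:
    """Stratified CV kNN: out-of-fold score = fraction of the k nearest
    (Euclidean, z-scored) training neighbours with label 1."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    _cv_checks(X, y, folds)
    min_class = np.bincount(y).min()
    min_train_class = int(min_class * (folds - 1) / folds)
    if k >= max(min_train_class, 1):
        raise KTooLargeError(
            f"k={k} >= smallest training-fold class (~{min_train_class})"
        )

    def fit_score(Xtr, ytr, Xte):
        model = KNeighborsClassifier(n_neighbors=k).fit(Xtr, ytr)
        return model.predict_proba(Xte)[:, 1], None

    scores, _ = _oof_scores(X, y, folds, seed, fit_score)
    auc = roc_auc(scores, y)
    ci = auc_bootstrap_ci(scores, y, B=B, seed=seed + 1)
    return ClassificationResult(method="knn", auc=auc, ci=ci, folds=folds,
                                seed=seed, params={"k": k},
                                scores=scores, labels=y)


def plsda_cv(
    X: Sequence[Sequence[float]],
    y: Sequence[int],
    n_components: int = 2,
    folds: int = 5,
    seed: int = 0,
    B: int = 1000,
    feature_names: Sequence[str] = FEATURE_ORDER,
) -> ClassificationResult:
    """Stratified CV PLSDA: labels encoded ±1, PLS regression scores as the
    continuous classifier output; signed importances are the fold-averaged
    regression coefficients on z-scored features."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    _cv_checks(X, y, folds)
    if not 1 <= n_components <= X.shape[1]:
        raise ValueError(
            f"n_components must be in 1..{X.shape[1]}, got {n_components}"
        )

    def fit_score(Xtr, ytr, Xte):
        pls = PLSRegression(n_components=n_components, scale=False)
        pls.fit(Xtr, 2.0 * ytr - 1.0)
        coefs = pls.coef_.ravel()
        return pls.predict(Xte).ravel(), (coefs, _vip_scores(pls))

    scores, extras = _oof_scores(X, y, folds, seed, fit_score)
    coef_mean = np.mean([c for c, _ in extras], axis=0)
    vip_mean = np.mean([v for _, v in extras], axis=0)
    auc = roc_auc(scores, y)
    ci = auc_bootstrap_ci(scores, y, B=B, seed=seed + 1)
    names = list(feature_names)
    return ClassificationResult(
        method="plsda", auc=auc, ci=ci, folds=folds, seed=seed,
        params={"n_components": n_components},
        importances=dict(zip(names, coef_mean.tolist())),
        vip=dict(zip(names, vip_mean.tolist())),
        scores=scores, labels=y,
    )


def _vip_scores(pls: PLSRegression) -> np.ndarray:
    """Variable importance in projection for a fitted PLS model."""
    T = pls.x_scores_
    W = pls.x_weights_
    Q = pls.y_loadings_
    p, a = W.shape
    ss = np.sum(T ** 2, axis=0) * (Q.ravel() ** 2)
    wnorm2 = (W / np.linalg.norm(W, axis=0)) ** 2
    return np.sqrt(p * (wnorm2 @ ss) / ss.sum())
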