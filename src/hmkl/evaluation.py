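"""Repeated stratified cross-validated AUC — the measurement protocol.

Performance is summarized as the averaged area under the ROC curve over
k-fold cross-validation repeated several times (defaults: 5 folds, 10
repeats).  AUC is computed as the midrank Mann–Whitney statistic: the
probability that a randomly chosen positive sample is scored above a
randomly chosen negative one, ties counting one half.  Folds are stratified
because the cohorts this protocol is aimed at are often heavily imbalanced,
where unstratified folds would frequently contain a single class.

Model factories are callables ``factory(X_train, y_train) -> scorer`` with
``scorer(X_test) -> real-valued scores``; everything a model learns (Gram
matrices, kernel weights, dual coefficients) is derived from the training
fold only, and held-out samples enter solely through cross-kernel blocks
against the training fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import mkl as _mkl
from .kernels import LabelledDataset, cross_kernel, gram
from .svm_dual import decision_values, solve_svm_dual

DEFAULT_FOLDS = 5
DEFAULT_REPEATS = 10


@dataclass
class CVReport:
    """Per-fold AUC values with their mean and standard deviation."""

    fold_aucs: np.ndarray  # (repeats, k), NaN marks an unusable fold
    mean_auc: float
    sd_auc: float
    config: dict

    @property
    def per_repeat_means(self) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.fold_aucs, axis=1)


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Midrank Mann–Whitney AUC of ``scores`` against ±1 ``labels``."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    pos = labels == 1
    neg = labels == -1
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    r = rankdata(scores)  # midranks
    u = r[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def stratified_folds(y: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    """Deterministic stratified partition of sample indices into ``k`` folds.

    Within each class, indices are shuffled and dealt round-robin, so fold
    class counts differ by at most one sample from the global ratio.  When a
    class has fewer members than ``k``, strict stratification is impossible
    and the partition degrades gracefully (with a warning): some folds then
    miss that class.
    """
    y = np.asarray(y)
    n = len(y)
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > n:
        raise ValueError(f"cannot make {k} folds from {n} samples")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    # rotate the dealing offset per class so small classes don't pile into fold 0
    offset = 0
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) < k:
            warnings.warn(
                f"class {cls} has {len(idx)} member(s) < {k} folds; "
                "stratification degrades", stacklevel=2)
        idx = rng.permutation(idx)
        for pos, i in enumerate(idx):
            folds[(pos + offset) % k].append(int(i))
        offset += len(idx) % k
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def cross_validate(
    dataset: LabelledDataset,
    model_factory,
    k: int = DEFAULT_FOLDS,
    repeats: int = DEFAULT_REPEATS,
    seed: int = 0,
) -> CVReport:
    """Repeated stratified k-fold CV of a model factory, scored by AUC.

    A fold whose held-out part contains a single class cannot be scored;
    its entry is NaN and excluded from the aggregate (with a warning).
    The aggregate mean/sd is taken over all ``repeats * k`` fold-level AUCs.
    """
    X, y = dataset.X, dataset.y
    fold_aucs = np.full((repeats, k), np.nan)
    for r in range(repeats):
        folds = stratified_folds(y, k, seed=seed + 1000003 * r)
        for f, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
            if len(np.unique(y[test_idx])) < 2:
                warnings.warn(
                    f"repeat {r} fold {f}: single-class test fold, AUC skipped",
                    stacklevel=2)
                continue
            scorer = model_factory(X[train_idx], y[train_idx])
            scores = scorer(X[test_idx])
            fold_aucs[r, f] = auc(scores, y[test_idx])
    vals = fold_aucs[~np.isnan(fold_aucs)]
    mean = float(np.mean(vals)) if vals.size else np.nan
    sd = float(np.std(vals, ddof=0)) if vals.size else np.nan
    return CVReport(fold_aucs, mean, sd,
                    {"k": k, "repeats": repeats, "seed": seed,
                     "stratified": True})


# ---------------------------------------------------------------------------
# model factories
# ---------------------------------------------------------------------------

def single_kernel_factory(spec, C: float = 1.0, tol: float = 1e-6):
    """Factory for a plain SVM on one kernel family."""

    def factory(X_train, y_train):
        K = gram(spec, X_train)
        sol = solve_svm_dual(K, y_train, C=C, tol=tol, check=False)

        def scorer(X_test):
            Kc = cross_kernel(spec, X_train, X_test)
            return decision_values(sol.alpha, sol.b, y_train, Kc)

        return scorer

    return factory


def mkl_factory(kernel_list, C: float = 1.0, **fit_kwargs):
    """Factory for the multiple-kernel model over a configured kernel list."""
    kernel_list = list(kernel_list)

    def factory(X_train, y_train):
        grams = [gram(s, X_train) for s in kernel_list]
        problem = _mkl.MKLProblem(kernel_list, grams, y_train, C=C)
        model = _mkl.fit(problem, X_train=X_train, **fit_kwargs)

        def scorer(X_test):
            return _mkl.predict(model, X_test)[0]

        scorer.model = model
        return scorer

    return factory


def compare_table(
    dataset: LabelledDataset,
    method_configs: list,
    k: int = DEFAULT_FOLDS,
    repeats: int = DEFAULT_REPEATS,
    seed: int = 0,
) -> pd.DataFrame:
    """CV-AUC comparison grid over a list of ``(name, factory)`` methods.

    Every method sees the same fold partitions (same seed).  A failing
    method yields a row with NaN values and the error message; the run
    continues.
    """
    rows = []
    for name, factory in method_configs:
        try:
            rep = cross_validate(dataset, factory, k=k, repeats=repeats,
                                 seed=seed)
            rows.append({
                "method": name, "mean_auc": rep.mean_auc, "sd_auc": rep.sd_auc,
                "display": f"{rep.mean_auc:.4f} ± {rep.sd_auc:.4f}",
                "error": "",
            })
        except Exception as exc:  # noqa: BLE001 - per-method isolation
            rows.append({"method": name, "mean_auc": np.nan, "sd_auc": np.nan,
                         "display": "failed", "error": str(exc)})
    return pd.DataFrame(rows)
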