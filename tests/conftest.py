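"""Shared fixtures and independent oracles.

The oracles deliberately take different routes from the implementation:
the QP oracle solves the dual with scipy's SLSQP on the explicit
constraint set, and the AUC oracle enumerates positive–negative pairs.
"""

import numpy as np
import pytest
from scipy.optimize import LinearConstraint, minimize

from hmkl.kernels import KernelSpec, gram


def slsqp_dual_objective(K, y, C, return_alpha=False):
    """Brute-force SVM dual optimum on a tiny instance via SLSQP."""
    K = np.asarray(K, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    Q = K * np.outer(y, y)

    def f(a):
        return 0.5 * a @ Q @ a - a.sum()

    def grad(a):
        return Q @ a - 1.0

    res = minimize(
        f, x0=np.full(n, min(C, 1.0) * 0.5), jac=grad, method="SLSQP",
        bounds=[(0.0, C)] * n,
        constraints=[{"type": "eq", "fun": lambda a: a @ y,
                      "jac": lambda a: y}],
        options={"maxiter": 1000, "ftol": 1e-14},
    )
    obj = -res.fun
    if return_alpha:
        return obj, res.x
    return obj


def pair_count_auc(scores, labels):
    """AUC by exhaustive pair counting: P(pos > neg) + 0.5 P(tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == -1]
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def random_toy_problem(seed, n=8, p=3, C=1.0):
    """Small strictly-positive dataset with balanced ±1 labels."""
    rng = np.random.default_rng(seed)
    X = np.abs(rng.normal(size=(n, p))) + 0.1
    y = np.array([1.0] * (n // 2) + [-1.0] * (n - n // 2))
    rng.shuffle(y)
    return X, y


@pytest.fixture
def toy_problem():
    return random_toy_problem(12345)


@pytest.fixture
def heterogeneous_specs():
    return [KernelSpec("hadamard", 1.0), KernelSpec("rbf", 1.0),
            KernelSpec("linear")]


def grams_for(specs, X):
    return [gram(s, X) for s in specs]
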