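"""Multiple kernel learning by reduced-gradient descent on the simplex.

The combined kernel is a convex combination ``K(d) = sum_m d_m K_m`` with
``d_m >= 0, sum_m d_m = 1``.  Writing ``f(d)`` for the optimal value of the
soft-margin SVM dual on ``K(d)``, the weights are learned by minimizing
``f`` over the simplex.  ``f`` is convex and differentiable with

    df/dd_m = -1/2 sum_ij a*_i a*_j y_i y_j K_m(x_i, x_j)

where ``a*`` is the inner dual optimum at ``d``.  The descent direction is
the negated reduced gradient: the gradient differenced against a pivot
coordinate ``mu`` (the largest weight), with coordinates at zero frozen
unless their reduced gradient favours re-entry, so every step stays in the
simplex's affine plane.  A golden-section line search over the feasible
step range completes each iteration; the run stops when the duality gap

    gap = f(d) - sum_i a*_i + 1/2 max_m sum_ij a*_i a*_j y_i y_j K_m

drops below tolerance (relative to ``sum_i a*_i``), which certifies
optimality of the weight vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .kernels import KernelMatrix, KernelSpec, check_psd, cross_kernel
from .svm_dual import SVMSolution, decision_values, solve_svm_dual

logger = logging.getLogger(__name__)

DEFAULT_TOL_GAP = 1e-3
DEFAULT_MAX_ITER = 200
#: inner dual solves spent per golden-section line search
LINE_SEARCH_EVALS = 12


# ---------------------------------------------------------------------------
# problem and model containers
# ---------------------------------------------------------------------------

@dataclass
class MKLProblem:
    """Base kernels, their Gram matrices over the training set, and labels."""

    kernel_list: list
    grams: list
    y: np.ndarray
    C: float = 1.0

    def __post_init__(self) -> None:
        if len(self.kernel_list) != len(self.grams) or not self.kernel_list:
            raise ValueError("kernel_list and grams must be non-empty and aligned")
        self.y = np.asarray(self.y, dtype=float)
        n = self.y.shape[0]
        vals = []
        for g in self.grams:
            V = g.values if isinstance(g, KernelMatrix) else np.asarray(g, float)
            if V.shape != (n, n):
                raise ValueError("Gram matrix shape does not match labels")
            vals.append(V)
        self._stack = np.ascontiguousarray(np.stack(vals))  # (M, N, N)

    @property
    def n_kernels(self) -> int:
        return len(self.kernel_list)

    @property
    def n_samples(self) -> int:
        return self.y.shape[0]

    def combined(self, d: np.ndarray) -> np.ndarray:
        return np.tensordot(np.asarray(d, float), self._stack, axes=1)

    def quad_forms(self, alpha: np.ndarray) -> np.ndarray:
        """``q_m = (a*y)' K_m (a*y)`` for every base kernel."""
        v = alpha * self.y
        return self._stack @ v @ v

    def validate_psd(self) -> None:
        for spec, g in zip(self.kernel_list, self.grams):
            ok, lam = check_psd(g)
            if not ok:
                name = spec.label() if isinstance(spec, KernelSpec) else str(spec)
                raise ValueError(f"kernel {name} is not PSD (min eig {lam:.3e})")


@dataclass
class MKLModel:
    """Fitted mixture: weights, dual coefficients, and training references."""

    d: np.ndarray
    alpha: np.ndarray
    b: float
    kernel_list: list
    X_train: np.ndarray
    y_train: np.ndarray
    sample_ids: list | None = None
    gap: float = np.nan
    f_value: float = np.nan
    converged: bool = True
    n_iter: int = 0
    trace: list = field(default_factory=list)

    def decision_function(self, X_new: np.ndarray) -> np.ndarray:
        return predict(self, X_new)[0]


# ---------------------------------------------------------------------------
# building blocks of one outer iteration
# ---------------------------------------------------------------------------

def objective_f(
    d: np.ndarray,
    problem: MKLProblem,
    C: float | None = None,
    tol: float = 1e-6,
    alpha0: np.ndarray | None = None,
) -> tuple[float, np.ndarray, float]:
    """``f(d)``: the SVM dual optimum on the combined kernel ``K(d)``.

    Returns ``(f_value, alpha_star, b)``; the inner solution is reused by
    the gradient and the duality gap.
    """
    d = np.asarray(d, dtype=float)
    C = problem.C if C is None else C
    K = problem.combined(d)
    sol = solve_svm_dual(K, problem.y, C=C, tol=tol, alpha0=alpha0, check=False)
    return sol.objective, sol.alpha, sol.b


def gradient_f(alpha_star: np.ndarray, y: np.ndarray, grams) -> np.ndarray:
    """Analytic gradient ``df/dd_m = -1/2 (a*y)' K_m (a*y)``.

    Each component is non-positive on PSD base kernels.
    """
    alpha_star = np.asarray(alpha_star, dtype=float)
    y = np.asarray(y, dtype=float)
    if alpha_star.shape != y.shape:
        raise ValueError("alpha and y shapes differ")
    v = alpha_star * y
    out = np.empty(len(grams))
    for m, g in enumerate(grams):
        V = g.values if isinstance(g, KernelMatrix) else np.asarray(g, float)
        out[m] = -0.5 * (v @ V @ v)
    return out


def reduced_gradient_direction(
    d: np.ndarray, grad: np.ndarray, mu: int
) -> np.ndarray:
    """Feasible descent direction from the reduced gradient.

    The reduced gradient differences each component against the pivot
    ``mu``; the direction is its negation, with zero-weight coordinates
    frozen when moving them would push below the boundary.  The result sums
    to zero (stays in the simplex plane) and satisfies ``<grad, D> <= 0``.
    """
    d = np.asarray(d, dtype=float)
    grad = np.asarray(grad, dtype=float)
    if d[mu] <= 0:
        raise ValueError("pivot coordinate must have positive weight")
    D = np.zeros_like(d)
    for m in range(len(d)):
        if m == mu:
            continue
        red = grad[m] - grad[mu]
        if d[m] <= 0 and red > 0:
            D[m] = 0.0  # frozen at the boundary; would move infeasibly
        else:
            D[m] = -red
    D[mu] = -np.sum(D)  # keeps the direction inside the simplex plane
    descent = float(grad @ D)
    if descent > 1e-12 * max(1.0, float(np.abs(grad).max())):
        raise RuntimeError(
            f"direction is not a descent direction (<grad, D> = {descent:.3e})"
        )
    return D


def line_search(
    d: np.ndarray,
    D: np.ndarray,
    problem: MKLProblem,
    C: float | None = None,
    f_current: float | None = None,
    alpha0: np.ndarray | None = None,
    n_evals: int = LINE_SEARCH_EVALS,
    inner_tol: float = 1e-6,
    gamma_cap: float | None = None,
):
    """Golden-section search for the step size along ``D``.

    Returns ``(gamma, d_next, f_next, alpha_next, b_next)``; ``gamma = 0``
    signals a stall (no feasible step decreased ``f``).  The upper limit of
    the search is the first step at which a weight hits zero.
    """
    d = np.asarray(d, dtype=float)
    D = np.asarray(D, dtype=float)
    neg = D < -1e-15
    if not np.any(neg):
        raise ValueError("direction has no feasible positive step")
    gamma_max = float(np.min(-d[neg] / D[neg]))
    if gamma_max <= 0:
        raise ValueError("no feasible positive step along direction")
    if gamma_cap is not None:
        gamma_max = min(gamma_max, gamma_cap)

    if f_current is None:
        f_current, alpha0, _ = objective_f(d, problem, C, tol=inner_tol,
                                           alpha0=alpha0)

    def project(gamma: float) -> np.ndarray:
        dn = np.clip(d + gamma * D, 0.0, None)
        return dn / dn.sum()

    cache_alpha = alpha0
    best = (0.0, f_current, alpha0, None)

    def evaluate(gamma: float):
        nonlocal best, cache_alpha
        dn = project(gamma)
        f, a, b = objective_f(dn, problem, C, tol=inner_tol, alpha0=cache_alpha)
        cache_alpha = a
        if f < best[1]:
            best = (gamma, f, a, b)
        return f

    # full step first (frequently optimal when a kernel is being switched off)
    evaluate(gamma_max)
    phi = 0.5 * (np.sqrt(5.0) - 1.0)
    lo, hi = 0.0, gamma_max
    x1 = hi - phi * (hi - lo)
    x2 = lo + phi * (hi - lo)
    f1, f2 = evaluate(x1), evaluate(x2)
    for _ in range(max(0, n_evals - 3)):
        if f1 <= f2:
            hi, x2, f2 = x2, x1, f1
            x1 = hi - phi * (hi - lo)
            f1 = evaluate(x1)
        else:
            lo, x1, f1 = x1, x2, f2
            x2 = lo + phi * (hi - lo)
            f2 = evaluate(x2)

    gamma, f_best, a_best, b_best = best
    if gamma == 0.0 or f_best >= f_current - 1e-12 * max(1.0, abs(f_current)):
        return 0.0, d, f_current, alpha0, None
    return gamma, project(gamma), f_best, a_best, b_best


def duality_gap(f_value: float, alpha_star: np.ndarray, y: np.ndarray,
                grams) -> float:
    """Optimality certificate for the weight vector.

    ``gap = f(d) - sum_i a*_i + 1/2 max_m (a*y)' K_m (a*y)``; zero at the
    optimum, and identically zero for a single kernel (the mixed quadratic
    form equals the max term, telescoping the dual objective).
    """
    alpha_star = np.asarray(alpha_star, dtype=float)
    y = np.asarray(y, dtype=float)
    v = alpha_star * y
    qmax = -np.inf
    for g in grams:
        V = g.values if isinstance(g, KernelMatrix) else np.asarray(g, float)
        qmax = max(qmax, float(v @ V @ v))
    return float(f_value - np.sum(alpha_star) + 0.5 * qmax)


# ---------------------------------------------------------------------------
# outer loop
# ---------------------------------------------------------------------------

def fit(
    problem: MKLProblem,
    C: float | None = None,
    tol_gap: float = DEFAULT_TOL_GAP,
    max_iter: int = DEFAULT_MAX_ITER,
    pivot_rule: str = "max_d",
    X_train: np.ndarray | None = None,
    sample_ids: list | None = None,
    inner_tol: float = 1e-6,
    line_search_evals: int = LINE_SEARCH_EVALS,
) -> MKLModel:
    """Learn the kernel mixture weights by reduced-gradient descent.

    Alternates between solving the SVM dual at the current ``d`` (warm
    started) and a reduced-gradient step on the simplex, until the relative
    duality gap falls below ``tol_gap`` or ``max_iter`` outer iterations.

    ``X_train``/``sample_ids`` are carried into the returned model so it can
    score new samples; they are not used by the optimization itself.
    """
    if pivot_rule != "max_d":
        raise ValueError(f"unknown pivot rule {pivot_rule!r}")
    C = problem.C if C is None else C
    M = problem.n_kernels
    d = np.full(M, 1.0 / M)
    trace: list[dict] = []

    f, alpha, b = objective_f(d, problem, C, tol=inner_tol)
    converged = False
    it = 0
    gap = np.inf
    for it in range(1, max_iter + 1):
        grad = gradient_f(alpha, problem.y, problem.grams)
        gap = duality_gap(f, alpha, problem.y, problem.grams)
        scale = max(float(np.sum(alpha)), 1e-12)
        trace.append({"iteration": it, "d": d.copy(), "f": f,
                      "gap": gap, "rel_gap": gap / scale})
        logger.debug("iter %d  f=%.6g  gap=%.3g  d=%s", it, f, gap,
                     np.array2string(d, precision=4))
        if gap <= tol_gap * scale:
            converged = True
            break
        mu = int(np.argmax(d))
        D = reduced_gradient_direction(d, grad, mu)
        if np.max(np.abs(D)) <= 1e-14 * max(1.0, float(np.abs(grad).max())):
            # stationary on the simplex but gap not closed: report honestly
            logger.warning("zero direction at non-optimal point (gap %.3g)", gap)
            break
        gamma, d_new, f_new, a_new, b_new = line_search(
            d, D, problem, C, f_current=f, alpha0=alpha,
            n_evals=line_search_evals, inner_tol=inner_tol)
        if gamma == 0.0:
            # refine once near the current point before giving up: tiny
            # improvements can be invisible at the coarse inner tolerance
            neg = D < -1e-15
            cap = 0.02 * float(np.min(-d[neg] / D[neg]))
            gamma, d_new, f_new, a_new, b_new = line_search(
                d, D, problem, C, f_current=f, alpha0=alpha,
                n_evals=2 * line_search_evals,
                inner_tol=min(inner_tol, 1e-9), gamma_cap=cap)
        if gamma == 0.0:
            logger.debug("line search stalled at iteration %d (gap %.3g)", it, gap)
            break
        if f_new > f + 1e-9 * max(1.0, abs(f)):
            raise RuntimeError(
                f"objective increased at iteration {it}: {f} -> {f_new}"
            )
        d, f, alpha = d_new, f_new, a_new
        b = b_new
        d = np.clip(d, 0.0, None)
        d /= d.sum()

    if not converged:
        # final certificate at the last accepted point
        gap = duality_gap(f, alpha, problem.y, problem.grams)
        converged = gap <= tol_gap * max(float(np.sum(alpha)), 1e-12)
        if not converged:
            logger.warning(
                "MKL stopped after %d iterations with relative gap %.3g",
                it, gap / max(float(np.sum(alpha)), 1e-12))

    return MKLModel(
        d=d, alpha=alpha, b=float(b), kernel_list=list(problem.kernel_list),
        X_train=X_train, y_train=problem.y.copy(), sample_ids=sample_ids,
        gap=float(gap), f_value=float(f), converged=converged,
        n_iter=it, trace=trace,
    )


def predict(model: MKLModel, X_new: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Score new samples under the fitted mixture.

    Returns ``(scores, labels)`` with
    ``score(x) = sum_i a_i y_i sum_m d_m k_m(x, x_i) + b`` and labels the
    sign of the score (0 mapped to +1).
    """
    if model.X_train is None:
        raise ValueError("model carries no training matrix; cannot score")
    # always a fresh buffer: scoring the training matrix itself must take
    # the same BLAS path as scoring new samples, so archived and in-memory
    # models produce identical bits
    X_new = np.array(X_new, dtype=float, copy=True)
    if X_new.ndim != 2 or X_new.shape[1] != model.X_train.shape[1]:
        raise ValueError(
            f"feature count mismatch: {X_new.shape} vs training "
            f"{model.X_train.shape}"
        )
    Kc = combined_cross(model.kernel_list, model.d, model.X_train, X_new)
    scores = decision_values(model.alpha, model.b, model.y_train, Kc)
    labels = np.where(scores >= 0, 1.0, -1.0)
    return scores, labels


def combined_cross(kernel_list, d, X_train, X_new) -> np.ndarray:
    """Mixed cross-kernel block ``sum_m d_m K_m(X_new, X_train)``."""
    Kc = np.zeros((X_new.shape[0], X_train.shape[0]))
    for w, spec in zip(d, kernel_list):
        if w > 0:
            Kc += w * cross_kernel(spec, X_train, X_new)
    return Kc


def check_kkt(model: MKLModel, problem: MKLProblem | None = None,
              C: float = 1.0) -> dict:
    """Residuals of the first-order optimality conditions at a model.

    Returns the violation of the equality constraint ``sum_i a_i y_i = 0``,
    of the box ``0 <= a_i <= C``, of the simplex constraint on ``d``, the
    margin residual on free support vectors, and (when the problem is
    supplied) the relative duality gap of the weight vector.
    """
    a, y = model.alpha, model.y_train
    C = problem.C if problem is not None else C
    report = {
        "equality": float(abs(np.sum(a * y))),
        "box": float(max(0.0, np.max(a - C), np.max(-a))),
        "simplex": float(abs(np.sum(model.d) - 1.0) + max(0.0, -np.min(model.d))),
    }
    if problem is not None:
        K = problem.combined(model.d)
        scores = decision_values(a, model.b, y, K)
        free = (a > 1e-8 * C) & (a < C * (1 - 1e-8))
        report["margin_free_sv"] = (
            float(np.max(np.abs(y[free] * scores[free] - 1.0)))
            if np.any(free) else 0.0
        )
        f = float(np.sum(a) - 0.5 * (a * y) @ K @ (a * y))
        gap = duality_gap(f, a, y, problem.grams)
        report["rel_gap"] = float(gap / max(np.sum(a), 1e-12))
    return report
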