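"""Kernel families and Gram-matrix construction.

Three kernel families are supported, chosen for their complementary view of
expression data:

* **Hadamard** — a harmonic-mean-style similarity
  ``K_beta(x_i, x_j) = sum_k |x_ik|^beta |x_jk|^beta / (2 (|x_ik|^beta + |x_jk|^beta))``,
  valid (positive semidefinite) on strictly positive data for beta != 0.
* **RBF** — the Gaussian ``exp(-||x_i - x_j||^2 / (2 sigma^2))``, sigma > 0.
* **linear** — the ordinary inner product ``x_i^T x_j``.

All Gram matrices are dense ``N x N`` arrays: in the intended regime the
number of samples is at most a few hundred while features number in the
thousands, so dense storage is the right trade.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

SYMMETRY_TOL = 1e-10
#: relative floor for the smallest eigenvalue in PSD validation
PSD_TOL = 1e-8

VALID_FAMILIES = ("hadamard", "rbf", "linear")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class LabelledDataset:
    """A sample-by-feature expression matrix with binary labels.

    Attributes
    ----------
    sample_ids : list of str
        One identifier per row of ``X``.
    X : ndarray of shape (N, p)
        Nonnegative expression intensities; samples as rows.
    y : ndarray of shape (N,)
        Class labels in {+1, -1}; both classes must be present.
    feature_ids : list of str
        One identifier per column of ``X``.
    """

    sample_ids: list
    X: np.ndarray
    y: np.ndarray
    feature_ids: list

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        n, p = self.X.shape
        if n < 2:
            raise ValueError(f"need at least 2 samples, got {n}")
        if p < 1:
            raise ValueError("need at least 1 feature")
        if len(self.sample_ids) != n or len(self.feature_ids) != p:
            raise ValueError("identifier lists do not match matrix shape")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("expression matrix contains non-finite values")
        if np.any(self.X < 0):
            i, j = np.argwhere(self.X < 0)[0]
            raise ValueError(
                f"negative expression value at sample {self.sample_ids[i]!r}, "
                f"feature {self.feature_ids[j]!r}"
            )
        if not set(np.unique(self.y)) <= {-1, 1}:
            raise ValueError("labels must be in {+1, -1}")
        if len(np.unique(self.y)) < 2:
            raise ValueError("both classes must be present")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class KernelSpec:
    """A kernel family together with its parameter.

    ``param`` is beta for the Hadamard family, sigma for RBF, and ``None``
    for the linear kernel.
    """

    family: str
    param: float | None = None

    def __post_init__(self) -> None:
        if self.family not in VALID_FAMILIES:
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.family == "hadamard":
            if self.param is None or self.param == 0:
                raise ValueError("hadamard kernel requires beta != 0")
        elif self.family == "rbf":
            if self.param is None or self.param <= 0:
                raise ValueError("rbf kernel requires sigma > 0")
        elif self.param is not None:
            raise ValueError("linear kernel carries no parameter")

    def label(self) -> str:
        if self.family == "linear":
            return "linear"
        sym = "beta" if self.family == "hadamard" else "sigma"
        return f"{self.family}({sym}={self.param:g})"


@dataclass
class KernelMatrix:
    """An ``N x N`` Gram matrix together with the spec that produced it."""

    values: np.ndarray
    spec: KernelSpec = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("Gram matrix must be square")
        asym = np.max(np.abs(self.values - self.values.T)) if self.values.size else 0.0
        if asym > SYMMETRY_TOL:
            raise ValueError(f"Gram matrix asymmetric beyond tolerance ({asym:.3g})")

    @property
    def n(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# kernel evaluation
# ---------------------------------------------------------------------------

def _check_nonnegative(X: np.ndarray, context: str) -> None:
    if np.any(X < 0):
        i, j = np.argwhere(X < 0)[0]
        raise ValueError(
            f"{context}: negative entry X[{i}, {j}] = {X[i, j]!r}; the Hadamard "
            "kernel is only valid for nonnegative data"
        )


def _hadamard_powers(X: np.ndarray, beta: float) -> tuple[np.ndarray, np.ndarray]:
    """Return |x|^beta with zeros kept at 0, plus a zero-entry mask.

    For beta < 0 a zero entry has no finite power; by the limiting
    convention any component touching such an entry contributes 0, which
    the caller enforces through the mask.
    """
    zero = X == 0
    A = np.zeros_like(X, dtype=float)
    nz = ~zero
    A[nz] = X[nz] ** beta
    return A, zero


def _hadamard_block(A1: np.ndarray, z1: np.ndarray, A2: np.ndarray,
                    z2: np.ndarray, beta: float) -> np.ndarray:
    """Row-wise evaluation of the Hadamard sum between two power matrices."""
    out = np.empty((A1.shape[0], A2.shape[0]))
    for i in range(A1.shape[0]):
        num = A1[i] * A2            # (M, p)
        den = A1[i] + A2
        with np.errstate(invalid="ignore", divide="ignore"):
            contrib = np.where(den > 0, num / (2.0 * den), 0.0)
        if beta < 0:
            # zero entries are undefined under a negative exponent: the
            # component is taken at its conventional limit 0
            contrib[:, :] = np.where(z1[i] | z2, 0.0, contrib)
        out[i] = contrib.sum(axis=1)
    return out


def hadamard_kernel(X: np.ndarray, beta: float) -> KernelMatrix:
    """Gram matrix of the Hadamard kernel with exponent ``beta``.

    Parameters
    ----------
    X : ndarray of shape (N, p)
        Nonnegative, finite expression values.
    beta : float
        Kernel exponent; must be nonzero.  Negative values emphasise small
        intensities, positive values large ones.
    """
    X = np.asarray(X, dtype=float)
    spec = KernelSpec("hadamard", beta)
    if not np.all(np.isfinite(X)):
        raise ValueError("hadamard_kernel: non-finite entries in X")
    _check_nonnegative(X, "hadamard_kernel")
    A, z = _hadamard_powers(X, beta)
    K = _hadamard_block(A, z, A, z, beta)
    K = 0.5 * (K + K.T)  # remove roundoff asymmetry
    return KernelMatrix(K, spec)


def rbf_kernel(X: np.ndarray, sigma: float) -> KernelMatrix:
    """Gaussian Gram matrix ``exp(-||x_i - x_j||^2 / (2 sigma^2))``."""
    X = np.asarray(X, dtype=float)
    spec = KernelSpec("rbf", sigma)
    d2 = _sq_dists(X, X)
    K = np.exp(-d2 / (2.0 * sigma**2))
    np.fill_diagonal(K, 1.0)
    K = 0.5 * (K + K.T)
    return KernelMatrix(K, spec)


def linear_kernel(X: np.ndarray) -> KernelMatrix:
    """Linear Gram matrix ``X X^T``."""
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("linear_kernel: non-finite entries in X")
    K = X @ X.T
    K = 0.5 * (K + K.T)
    return KernelMatrix(K, KernelSpec("linear"))


def _sq_dists(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    a2 = np.sum(A**2, axis=1)[:, None]
    b2 = np.sum(B**2, axis=1)[None, :]
    d2 = a2 + b2 - 2.0 * (A @ B.T)
    return np.maximum(d2, 0.0)


def gram(spec: KernelSpec, X: np.ndarray) -> KernelMatrix:
    """Symmetric Gram matrix of ``X`` under ``spec``."""
    if spec.family == "hadamard":
        return hadamard_kernel(X, spec.param)
    if spec.family == "rbf":
        return rbf_kernel(X, spec.param)
    return linear_kernel(X)


def cross_kernel(spec: KernelSpec, X_train: np.ndarray,
                 X_test: np.ndarray) -> np.ndarray:
    """``M x N`` kernel block between held-out and training samples.

    Entry ``(i, j)`` is ``k(x_test_i, x_train_j)``.  With
    ``X_test is X_train`` this reproduces the symmetric Gram matrix.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    if X_train.ndim != 2 or X_test.ndim != 2 or X_train.shape[1] != X_test.shape[1]:
        raise ValueError(
            f"cross_kernel: feature counts differ "
            f"({X_test.shape} vs {X_train.shape})"
        )
    if spec.family == "hadamard":
        _check_nonnegative(X_train, "cross_kernel")
        _check_nonnegative(X_test, "cross_kernel")
        A1, z1 = _hadamard_powers(X_test, spec.param)
        A2, z2 = _hadamard_powers(X_train, spec.param)
        return _hadamard_block(A1, z1, A2, z2, spec.param)
    if spec.family == "rbf":
        d2 = _sq_dists(X_test, X_train)
        return np.exp(-d2 / (2.0 * spec.param**2))
    return X_test @ X_train.T


def check_psd(K: KernelMatrix | np.ndarray, tol: float = PSD_TOL) -> tuple[bool, float]:
    """Validate positive semidefiniteness of a symmetric Gram matrix.

    Returns ``(ok, min_eigenvalue)`` where ``ok`` is true iff the smallest
    eigenvalue is at least ``-tol * max(1, largest eigenvalue)``.
    """
    V = K.values if isinstance(K, KernelMatrix) else np.asarray(K, dtype=float)
    asym = np.max(np.abs(V - V.T))
    if asym > 1e-8 * max(1.0, np.max(np.abs(V))):
        raise ValueError(f"check_psd: input asymmetric beyond tolerance ({asym:.3g})")
    w = scipy.linalg.eigvalsh(0.5 * (V + V.T))
    lo, hi = w[0], w[-1]
    return bool(lo >= -tol * max(1.0, hi)), float(lo)
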