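"""Expression-like synthetic datasets with controlled geometry.

Each generator emulates the shape regime of microarray outcome cohorts —
far more features than samples, strictly positive skewed intensities,
binary and possibly imbalanced labels — while planting a known geometric
relationship between features and labels:

* :func:`make_linear` — labels follow a sparse linear score, so a linear
  kernel suffices;
* :func:`make_radial` — labels follow the distance from a centre in a
  latent 3-D subspace (spherical shells), which a Gaussian kernel separates
  and a linear one cannot;
* :func:`make_null` — labels independent of all features, for calibration
  of the measurement protocol (any honest pipeline must land near AUC 0.5).

Base intensities are log-normal to mimic the positivity and right skew of
microarray intensities.  No gene–gene correlation structure or batch
effects are simulated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kernels import LabelledDataset

STRUCTURES = ("linear", "radial", "hadamard_friendly", "null")


@dataclass
class SynthSpec:
    """Recipe for one synthetic cohort.

    ``noise_sd`` is the difficulty knob: label noise (in units of the score
    spread) for the linear design, noise-feature spread for the radial one.
    ``gap`` (radial only) is the separation of the two shell radii in units
    of the shell width; 0 makes the classes indistinguishable.
    """

    n_samples: int = 60
    n_features: int = 1000
    class_balance: float = 0.5
    structure: str = "linear"
    noise_sd: float = 0.25
    seed: int = 0
    gap: float = 1.0

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise ValueError("need at least 4 samples")
        if self.n_features < 2:
            raise ValueError("need at least 2 features")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must be in (0, 1)")
        if self.structure not in STRUCTURES:
            raise ValueError(f"unknown structure {self.structure!r}")


def _ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i}" for i in range(n)]


def _n_positive(spec: SynthSpec) -> int:
    n_pos = int(round(spec.class_balance * spec.n_samples))
    return min(max(n_pos, 1), spec.n_samples - 1)


def _labels_from_score(score: np.ndarray, n_pos: int) -> np.ndarray:
    """±1 labels with exactly ``n_pos`` positives: the top-scoring samples."""
    y = -np.ones(len(score))
    y[np.argsort(-score, kind="stable")[:n_pos]] = 1.0
    return y


#: additive class separation of make_linear, in units of the sparse
#: score's spread; 4 keeps noise-free cohorts cleanly separable out of
#: sample across the supported shape regimes
LINEAR_EFFECT = 4.0


def make_linear(spec: SynthSpec) -> LabelledDataset:
    """Labels from a sparse linear score over 5% of the features.

    A latent class variable shifts the informative features additively
    (effect ``LINEAR_EFFECT`` in units of the sparse score's spread), the
    matrix is shifted to stay nonnegative, and the reported labels are the
    thresholded latent class plus Gaussian label noise of spread
    ``noise_sd``.  With ``noise_sd = 0`` the labels equal the sign of an
    exact linear function of X, so the classes are linearly separable by
    construction — in every training and held-out split alike.
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_samples, spec.n_features
    X = np.exp(rng.normal(0.0, 1.0, size=(n, p)))
    n_inf = max(1, int(round(0.05 * p)))
    inf_idx = rng.choice(p, size=n_inf, replace=False)
    w = rng.choice([-1.0, 1.0], size=n_inf) * rng.uniform(0.5, 1.5, size=n_inf)
    n_pos = _n_positive(spec)
    latent = np.concatenate([np.ones(n_pos), -np.ones(n - n_pos)])
    latent = latent[rng.permutation(n)]
    # plant the separation along w in the informative block
    base_score = (X[:, inf_idx] - X[:, inf_idx].mean(axis=0)) @ w
    scale = base_score.std() or 1.0
    shift = LINEAR_EFFECT * scale / (w @ w)
    X[:, inf_idx] += shift * np.outer(latent, w)
    lo = X.min()
    if lo < 0:  # keep the matrix in the admissible nonnegative range
        X += -lo + 0.01
    y = _labels_from_score(latent + spec.noise_sd * rng.normal(size=n), n_pos)
    return LabelledDataset(_ids("S", n), X, y, _ids("g", p))


def make_radial(spec: SynthSpec) -> LabelledDataset:
    """Labels from spherical shells in a latent 3-D subspace.

    Three feature columns carry the signal: samples sit on shells of radius
    ``|N(1, 0.3)|`` (class +1) or ``|N(1 + gap, 0.3)|`` (class −1) around a
    common positive centre, so the class depends on the distance from the
    centre, not on any linear functional.  The remaining columns are
    log-normal noise of spread ``noise_sd``.
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_samples, spec.n_features
    if p < 3:
        raise ValueError("radial design needs at least 3 features")
    n_pos = _n_positive(spec)
    y = np.concatenate([np.ones(n_pos), -np.ones(n - n_pos)])
    y = y[rng.permutation(n)]
    radii = np.where(y > 0,
                     np.abs(rng.normal(1.0, 0.3, size=n)),
                     np.abs(rng.normal(1.0 + spec.gap, 0.3, size=n)))
    dirs = rng.normal(size=(n, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    centre = 6.0
    signal = np.clip(centre + radii[:, None] * dirs, 1e-6, None)
    X = np.exp(rng.normal(0.0, max(spec.noise_sd, 1e-12), size=(n, p)))
    sig_idx = rng.choice(p, size=3, replace=False)
    X[:, sig_idx] = signal
    return LabelledDataset(_ids("S", n), X, y, _ids("g", p))


def make_null(spec: SynthSpec) -> LabelledDataset:
    """Features independent of labels: the calibration design."""
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_samples, spec.n_features
    X = np.exp(rng.normal(0.0, 1.0, size=(n, p)))
    n_pos = _n_positive(spec)
    y = np.concatenate([np.ones(n_pos), -np.ones(n - n_pos)])
    y = y[rng.permutation(n)]
    return LabelledDataset(_ids("S", n), X, y, _ids("g", p))


def generate(spec: SynthSpec) -> LabelledDataset:
    """Dispatch on ``spec.structure``."""
    if spec.structure == "radial":
        return make_radial(spec)
    if spec.structure == "null":
        return make_null(spec)
    # "hadamard_friendly" shares the sparse-linear design on positive data:
    # the component-wise kernel sees the same informative coordinates
    return make_linear(spec)
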