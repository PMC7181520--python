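# Methods

## Model and assumptions

The classifier is a soft-margin SVM whose Gram matrix is a convex
combination K(d) = Σₘ dₘKₘ of base kernels, with d on the probability
simplex. The simplex constraint acts as an ℓ₁ penalty across kernels and
therefore encourages sparse mixtures: kernels that do not help the margin
objective are driven to weight zero. Three families are supported:

* **Hadamard** (parameter β ≠ 0): Σₖ |x_ik|^β|x_jk|^β / (2(|x_ik|^β+|x_jk|^β)).
  Positive semidefinite on nonnegative data only, which is why the data
  containers reject negative entries outright rather than silently taking
  absolute values. Components touching a zero entry are assigned their
  limiting value 0 (for β < 0 the power is undefined at 0; the continuous
  extension keeps the Gram finite). Note the identity
  K_β(X) = K₁(X∘^β): the exponent can be folded into the data.
* **RBF** (σ > 0): the standard Gaussian exp(−‖Δ‖²/2σ²).
* **linear**: XXᵀ.

All Gram matrices are dense (the intended regime is N ≤ a few hundred
samples, p up to ~6×10⁴ features) and validated for symmetry (1e−10) and
positive semidefiniteness (min eigenvalue ≥ −1e−8·max(1, max eigenvalue)).
No normalization is applied to the base Grams inside the fit: the mixture
operates on the kernels exactly as defined, so the learned weights absorb
scale differences between families. (Trace-normalizing the base kernels
was evaluated and rejected: on weak-signal data it promotes identity-like
Grams, which are the best *training-margin* interpolators and the worst
generalizers.)

## Inner solver

The SVM dual (maximize Σα − ½αᵀ(yyᵀ∘K)α subject to 0 ≤ α ≤ C, yᵀα = 0)
is solved by sequential minimal optimization with second-order working-set
selection; the hot loop is numba-compiled. The stopping threshold on the
maximal KKT violation (default 1e−6) is multiplied by
max(1, C·median(diag K)) so that solver effort is invariant to the
arbitrary overall scale of the Gram matrix. Warm starts reuse the previous
α (always feasible, since feasibility does not depend on K), which makes
the outer line searches cheap. The intercept is averaged over free support
vectors, falling back to the midpoint of the feasible KKT interval when
every support vector sits on the box. C defaults to 1.0 and is exposed
everywhere; the comparisons this package is designed for hinge on kernels,
not on C.

## Outer loop (weight learning)

From the inner optimum α*, the gradient is ∂f/∂dₘ = −½(α*∘y)ᵀKₘ(α*∘y).
The descent direction is the negated reduced gradient with the pivot μ
chosen as the largest weight (which guarantees d_μ > 0): active
coordinates get D_m = ∂f/∂d_μ − ∂f/∂dₘ, zero-weight coordinates are frozen
unless their reduced gradient favours re-entry, and D_μ closes the sum to
zero so every step stays in the simplex plane. A runtime guard asserts
⟨∇f, D⟩ ≤ 0. The step size comes from a golden-section search on
[0, γ_max] (γ_max = first coordinate to hit zero; 12 inner solves, the
full step evaluated first since kernel switch-offs are common); on a stall
the search is retried once near the current point (2% of the interval,
tighter inner tolerance) before the run stops. Convergence is declared
when the duality gap

    gap = f(d) − Σα* + ½ maxₘ (α*∘y)ᵀKₘ(α*∘y)

falls below 1e−3 × Σα* (relative gap, configurable; the fits compared
against dense grid oracles in the acceptance suite use 1e−4 with a 1e−8
inner tolerance, matching the precision of that comparison). For a single
kernel the gap telescopes to zero identically. Runs that stop without the
certificate are flagged (`converged=False`) and logged, never silently
accepted; the objective trace is monotone by construction and retained on
the model. Weights are initialized uniform (1/M), and the formulas accept
any M ≥ 1 so the 21-kernel configuration (one linear, ten RBF, ten
Hadamard) is expressible.

## Parameter selection (PSO)

(β, σ) are selected by a canonical inertia–cognitive–social particle
swarm: v ← ωv + c₁ψ₁(p_best − z) + c₂ψ₂(g_best − z), z ← z + v, with ψ
drawn per particle and per coordinate. Defaults are 3 particles, 20
generations, c₁ = 1.5, c₂ = 1.7; ω = 0.8 (standard inertia range; the
selection quality is assessed by known-optimum recovery, not by matching
any particular trajectory). σ spans five orders of magnitude and is
searched on a log₁₀ scale internally; bounds default to β ∈ [−1, 1],
σ ∈ [0.01, 1000] (the hulls of the experimental grids), and β is clamped
away from the invalid value 0 by a ±1e−3 band. The default fitness is the
mean 5-fold CV AUC of the full mixture fit at the candidate parameters
(cached on the rounded position); a cheaper margin-objective fitness is
available. Tuning can run once globally or per training fold; the global
mode is the default in the bundled pipeline for cost reasons and because
the calibration experiments probe the CV measurement, not the tuning
protocol.

## Evaluation protocol

AUC is the midrank Mann–Whitney statistic (probability a random positive
outranks a random negative, ties ½). Folds are stratified by class —
the intended cohorts are heavily imbalanced (e.g. 11 vs 96), where
unstratified 5-fold splits frequently contain a single class — and dealt
round-robin after a seeded within-class shuffle, so partitions are
deterministic per seed. The headline number is the mean ± SD over all
repeats × folds fold-level AUCs (default 10 × 5). Kernel parameters,
mixture weights and dual coefficients are learned inside each training
fold; held-out samples enter only through cross-kernel blocks against the
training fold. A test fold that ends up single-class is recorded as
missing and excluded from the aggregate, with a warning.

## Synthetic cohorts

The generators emulate the shape regime of expression cohorts — features ≫
samples, strictly positive log-normal intensities, exact class balance as
requested — with a planted geometry per design:

* `make_linear`: 5% of features are informative; a latent class variable
  shifts them additively along a sparse weight vector with effect size 4×
  the sparse score's spread (the matrix is then shifted to remain
  nonnegative). This keeps noise-free cohorts linearly separable in every
  train/test split, so a correct linear-kernel pipeline reaches CV AUC 1.0.
  `noise_sd` perturbs a latent score before thresholding, decoupling the
  reported labels from the planted class at a controlled rate (the
  difficulty knob).
* `make_radial`: three feature columns place samples on spherical shells
  of radius |N(1, 0.3)| (class +1) vs |N(1+gap, 0.3)| (class −1) around a
  common positive centre; remaining columns are log-normal noise of spread
  `noise_sd`. Gaussian kernels separate the classes, linear ones cannot;
  `gap → 0` removes the signal entirely.
* `make_null`: labels independent of all features — the calibration
  design; any honest pipeline must land near AUC 0.5.

What these designs do **not** emulate: gene–gene correlation structure,
batch effects, probe-level noise, or heavy-tailed outlier samples.
Passing tests therefore certify the solvers and the honesty of the
measurement protocol, not performance on any real cohort.

## Verification quantities (scripts/acceptance.py)

All checks are recomputed from scratch at fixed, stated problem sizes
(chosen to exercise the contracts at full strength while the whole script
completes in well under a minute): single-kernel equivalence on 20 random
problems (N ≤ 30); gradient vs central finite differences on 10 three-kernel
problems (N = 8); duality-gap certificates on 5 mixtures (N = 14);
two-kernel optima vs a 101-point simplex grid with an SLSQP oracle (10
seeds, N = 8); the hand-solvable two-point dual; Hadamard PSD-ness over 50
positive cohorts × the 6-point β grid; kernel-selection rates on radial
(n = 60, p = 10) and linear (n = 40, p = 1000, plus a permuted-features
noise kernel) cohorts over 10 seeds each; AUC vs pair counting on 100
instances; the swarm-tuned pipeline on 10 null cohorts (n = 48, p = 60,
5-fold × 10 evaluation); and swarm recovery of a known concave optimum
(10 particles, 50 generations, 5 seeds).

## Known limitations

* The margin objective is a training criterion: on data whose Gram
  matrices are dominated by noise directions it can retain a weakly
  informative kernel that a CV criterion would discard. The selection
  experiments therefore use cohorts with genuine planted structure.
* The reduced-gradient loop can stall short of its certificate on
  degenerate (label-free) problems where objective differences fall below
  solver precision; such runs are flagged, and their predictions remain
  valid SVM solutions at the final weights.
* Dense Gram matrices bound the practical sample count at a few thousand;
  nothing in the package is out-of-core.
* Feature normalization is deliberately opt-in (`none` by default;
  per-feature min-max to [ε, 1] and log2(1+x) offered): the method's
  validity claim for the Hadamard kernel rests on positive inputs, and no
  default transformation is assumed.
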