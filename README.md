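# hmkl — heterogeneous multiple kernel learning for expression-based outcome classification

`hmkl` implements a support-vector classifier whose kernel is a **learned
convex combination of heterogeneous kernels** — Hadamard, Gaussian (RBF)
and linear — for binary outcome prediction from gene-expression-like data
(bulk microarray or single-cell matrices: far more features than samples,
strictly positive intensities, often imbalanced classes). It is aimed at
computational biologists who want a kernel method that *selects its own
kernel* instead of committing to one up front.

## The model

Given training samples x₁,…,x_N with labels yᵢ ∈ {+1, −1}, the combined
kernel is

    K(xᵢ, xⱼ) = Σₘ dₘ Kₘ(xᵢ, xⱼ),   dₘ ≥ 0,  Σₘ dₘ = 1,

with base kernels

* **Hadamard** K_β(xᵢ,xⱼ) = Σₖ |x_ik|^β |x_jk|^β / (2(|x_ik|^β + |x_jk|^β)),
  a harmonic-mean similarity valid on positive data (β ≠ 0),
* **RBF** K_σ(xᵢ,xⱼ) = exp(−‖xᵢ−xⱼ‖² / 2σ²),
* **linear** K(xᵢ,xⱼ) = xᵢᵀxⱼ.

Writing f(d) for the optimal value of the soft-margin SVM dual on K(d),

    f(d) = max_α Σᵢ αᵢ − ½ Σᵢⱼ αᵢαⱼyᵢyⱼ K(d)(xᵢ,xⱼ),
           0 ≤ αᵢ ≤ C,  Σᵢ αᵢyᵢ = 0,

the mixture weights minimize f over the probability simplex by a
**reduced-gradient descent** (∂f/∂dₘ = −½ Σᵢⱼ α*ᵢα*ⱼyᵢyⱼKₘ(xᵢ,xⱼ),
differenced against a pivot coordinate), alternating with the inner dual
solve and stopping on the duality-gap certificate

    DualGap = f(d) − Σᵢ α*ᵢ + ½ maxₘ Σᵢⱼ α*ᵢα*ⱼyᵢyⱼKₘ(xᵢ,xⱼ).

The kernel parameters (β, σ) are selected by **particle swarm
optimization** (defaults: 3 particles, 20 generations, c₁ = 1.5,
c₂ = 1.7) against cross-validated AUC, and performance is reported as the
averaged AUC of stratified 5-fold cross-validation run 10 times.

## Worked example

Radial synthetic data — labels depend on the distance from a centre in a
latent 3-D subspace, so the Gaussian kernel should win:

```python
import numpy as np
from hmkl import (SynthSpec, make_radial, KernelSpec, MKLProblem, gram, mkl,
                  cross_validate, mkl_factory, single_kernel_factory)

ds = make_radial(SynthSpec(n_samples=60, n_features=10,
                           structure="radial", seed=0))
specs = [KernelSpec("hadamard", 1.0), KernelSpec("rbf", 1.0),
         KernelSpec("linear")]
grams = [gram(s, ds.X) for s in specs]
model = mkl.fit(MKLProblem(specs, grams, ds.y, C=1.0), X_train=ds.X)
print("weights d =", np.round(model.d, 4))

rep = cross_validate(ds, mkl_factory(specs), k=5, repeats=10, seed=0)
print(f"mixed-kernel CV AUC = {rep.mean_auc:.4f} ± {rep.sd_auc:.4f}")
```

prints

```
weights d = [0. 1. 0.]
mixed-kernel CV AUC = 0.9583 ± 0.0394
```

The mixture puts all weight on the RBF kernel and matches its
single-kernel performance (0.9589 ± 0.0390), while the Hadamard and
linear kernels alone sit at chance (0.51, 0.50) — the learned weights
identify the kernel that matches the data geometry.

The same flow from the shell:

```bash
hmkl simulate --structure radial --n-samples 60 --n-features 10 --seed 0 --out demo
hmkl evaluate demo_matrix.tsv demo_labels.tsv \
     --kernels "hadamard:1,rbf:1,linear" --repeats 10 --seed 0 --out eval_out
# mean AUC = 0.9589 ± 0.0390 (5-fold × 10)
hmkl tune demo_matrix.tsv demo_labels.tsv --seed 0 --out tune_out
hmkl fit demo_matrix.tsv demo_labels.tsv --kernels "hadamard:1,rbf:1,linear" --out fit_out
# fitted: d = [0.0, 1.0, 0.0]
```

`hmkl compare` produces the kernel-configuration comparison grid
(single-kernel SVMs over the σ/β grids, 3-kernel and 21-kernel mixtures);
`hmkl predict` scores new samples with an archived model. Input format:
delimited text, samples as rows with one header row of feature names plus
a two-column sample-to-label file (`--transpose` for genes-as-rows files).

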