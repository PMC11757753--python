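# turingrmt

Random-matrix analysis of how robustly reaction–diffusion networks form
Turing patterns.

Biological gene-regulatory networks are larger and messier than the
two-species activator–inhibitor models in which Turing instabilities are
usually studied, and the classical Turing conditions demand implausible
fine-tuning.  This package takes the statistical route: the reaction part
of a network with `N` molecular species is represented by a random
Jacobian

```
J0 = G − I,          Var(g_ij) = σ²,  g_ii = 0,
```

whose off-diagonal entries are zero-mean Gaussians (optionally sparsified
with connectivity `C`) and whose identity part models uniform degradation.
By the circular law the eigenvalues fill a disk of radius `γ = σ√(NC)`
centred at −1.  Two species diffuse with constants `D₁, D₂`; all others
are immobile.  A wave-like perturbation of wavenumber `k` gives the
modified Jacobian

```
J(k) = J0 − k² D,    D = diag(D₁, D₂, 0, …, 0),
```

and the dispersion relation `Re λ_max(k)` classifies each sampled system
as stable, unstable without diffusion, Turing I (interior positive peak,
stable again as `k → ∞`), Turing II (still unstable at the end of the
`k` grid), or Turing–Hopf (oscillatory leading eigenvalue at the peak).

Monte-Carlo surveys over `(N, σ²)`, `(N, γ)` and `(D₁, D₂)` grids locate
the *optimal network size*: the number of species whose row of the
size–variance heat map collects the largest share of Turing-I systems —
a trade-off between small networks being stable without diffusion and
large networks being unstable with it.  A companion module grounds the
random-matrix abstraction in mechanistic Hill-function gene circuits:
Latin-hypercube parameter screens of small signed topologies produce the
empirical Jacobian-element distributions (summarised by location-scale
beta fits) that motivate the Gaussian ensemble.

## Worked example

```python
import numpy as np
from turingrmt import (DiffusionSpec, KGrid, extract_optimal_size,
                       run_size_variance_heatmap)

heat = run_size_variance_heatmap(
    n_values=np.arange(2, 13),
    sigma2_values=np.linspace(0.02, 1.0, 25),
    diff=DiffusionSpec(1.0, 10.0),
    n_samples=500,
    seed=1,
    k_grid=KGrid(k_max=10.0, step=0.01),
)
opt = extract_optimal_size(heat)
print(f"optimal network size: N = {opt.n_opt}")
print(opt.to_dataframe().head(6).to_string(index=False))
```

prints (a few minutes on one core)

```
optimal network size: N = 6
 N  turing_I_share_percent  peak_turing_I_percent  peak_sigma2
 2                0.000000                    0.0     0.020000
 3                5.097087                    0.6     0.673333
 4               14.563107                    1.8     1.000000
 5               19.417476                    2.0     0.795833
 6               22.330097                    1.8     0.836667
 7               10.922330                    1.4     0.265000
```

Each row gives that network size's percentage share of all Turing-I
systems found across the heat map (shares sum to 100 over the scanned
sizes), the largest single-cell Turing-I percentage in the row, and the
interaction variance at which it occurred.  Networks with two nodes never
pattern in this model (a determinant identity forbids it), and the share
peaks at a handful of species — five or six, whose difference sits at the
sampling noise floor at 500 matrices per cell — before decaying for large
networks, whose eigenvalue disks cross into instability without
diffusion.

The same surveys run from the shell:

```
turingrmt survey --config config.yaml --seed 1 --out results/
turingrmt screen-hill --topology src/turingrmt/data/topologies/activator_inhibitor_2node.yaml \
    --samples 10000 --out results/
turingrmt selftest
```

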