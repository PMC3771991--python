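# pcgc — partially conditioned Granger causality for large multivariate time series

Granger causality (GC) calls a signal *x* a driver of *y* when the past of
*x* improves the prediction of *y* beyond what *y*'s own past (and the past
of any conditioning signals) already achieves:

```
gc(x -> y | Z) = ln( sigma²_restricted / sigma²_unrestricted )
```

where the restricted AR model regresses *y(t)* on the lagged *y* and *Z*,
the unrestricted model adds the lagged *x*, and significance comes from the
standard F-test on the two residual sums of squares.  Conditioning on *Z*
is what separates direct from merely mediated influence — but in
high-dimensional recordings (e.g. tens of thousands of voxel time series
from resting-state fMRI, a few hundred time points each) conditioning on
*everything* is impossible: the design matrix becomes singular and the
coefficients meaningless.  This package implements two practical
conditioning schemes:

* **PCGC^d** — condition each driver on the small set of variables most
  informative about it, grown greedily under the Gaussian mutual
  information `MI(A;B) = ½[ln det Σ_A + ln det Σ_B − ln det Σ_{A∪B}]`,
  with the knee of the information-gain curve suggesting the set size
  (default n_d = 10).
* **PCGC^t / PCGC^ti** — condition on *community-aggregated* mean signals:
  a two-level Louvain partition of the absolute correlation matrix gives
  systems and subsystems; the driver's own system is conditioned at
  subsystem resolution, every other system as one aggregate.  Regressing
  on a group mean constrains the group's AR coefficients to one shared
  weight, which defuses the multicollinearity of redundant neighbours.
  The `ti` variant leaves the driver inside its aggregate (cheaper, and
  nearly identical in value).

Around the estimators the library provides the full supporting pipeline
for fMRI-style data: temporal preprocessing (frame-wise-displacement
scrubbing, nuisance regression, detrending, 0.01–0.08 Hz band-pass),
blind hemodynamic deconvolution by point-process event detection +
canonical-HRF fitting + Wiener inversion, seed-based and all-pairs
causality mapping, directed-network statistics (in/out degree,
betweenness, clustering, normalized nodal values, hub scores,
cluster-extent filtering), and a fully synthetic modular AR benchmark
with known ground truth.  It is intended for researchers analysing
directed ("effective") connectivity in neuroimaging or any other domain
with many short, redundant time series.

## Worked example

A three-variable causal chain `x -> w -> y` (no direct `x -> y` link;
`examples/conditional_vs_pairwise.py`):

```python
import numpy as np
from pcgc import TimeSeriesSet, conditional_gc

rng = np.random.default_rng(0)
t = 5000
x, w, y = np.zeros(t), np.zeros(t), np.zeros(t)
e = rng.standard_normal((t, 3))
for i in range(1, t):
    x[i] = 0.5 * x[i - 1] + e[i, 0]
    w[i] = 0.3 * w[i - 1] + 0.8 * x[i - 1] + e[i, 1]
    y[i] = 0.3 * y[i - 1] + 0.8 * w[i - 1] + e[i, 2]

ts = TimeSeriesSet(np.column_stack([x, w, y]), labels=["x", "w", "y"])
pairwise = conditional_gc(ts, 0, 2)
conditioned = conditional_gc(ts, 0, 2, z=[1])  # mediator in Z
print(f"pairwise    gc(x->y)       = {pairwise.gc:.4f}  p = {pairwise.p_value:.2e}")
print(f"conditioned gc(x->y | w)   = {conditioned.gc:.4f}  p = {conditioned.p_value:.3f}")
```

prints

```
pairwise    gc(x->y)       = 0.0598  p = 7.00e-67
conditioned gc(x->y | w)   = 0.0000  p = 0.788
```

The pairwise index is strongly "significant" although no direct link
exists; one conditioning variable removes it.  At scale the same effect is
what the benchmark shows (`examples/benchmark_recovery.py`): on the
6-module AR system whose only true module-level link is Module 1 →
Module 2, the repeated-simulation Wilcoxon protocol returns

```
pairwise  links: M1->M2, M2->M1   TP=1 FP=1 FN=0
pcgc_d    links: M1->M2           TP=1 FP=0 FN=0
pcgc_t    links: M1->M2           TP=1 FP=0 FN=0
```

The other examples demonstrate blind deconvolution
(`examples/deconvolve_demo.py`: 91% of recovered spikes within ±1 TR of
the true event times on noisy synthetic BOLD) and volumetric seed mapping
(`examples/seed_mapping.py`: only the planted driven module shows incoming
influence).

A thin CLI mirrors the pipeline stages for shell use:
`pcgc preprocess|deconvolve|seedmap|network|centrality|benchmark --help`.

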