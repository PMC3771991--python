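"""Simulation benchmark: modular AR system with one known directed link.

The validation system has 6k observed variables built from a pair of
coupled AR(1) latents and four auxiliary groups:

* latents:  x1(t) = a x1(t-1) + eps1(t),
            x2(t) = a x2(t-1) + b x1(t-1) + eps2(t)
  so by construction x1 drives x2 and x2 does not drive x1;
* Module 1 (k variables): c_i x1(t) + noise — shared information of x1;
* Module 2 (k variables): c_i x2(t) + noise — shared information of x2;
* Modules 3, 4 and 5 (k each): equal-time correlated groups, each on its
  own independent white latent.  (Setting ``module3_lag_coupled`` rides
  Module 3 on x1 delayed one step instead; that variant makes naive
  pairwise analysis see Module 1 -> Module 3, but it also hands Module 3
  genuine predictive information about x2, i.e. a second true link — so
  it is not the default study condition.)
* Module 6 (k): pure independent noise.

Mixing coefficients c are drawn i.i.d. Gaussian with mean 0.3 and variance
0.3; observation noises are unit variance.  The module-level ground truth
is a single directed link, Module 1 -> Module 2.

The decision protocol repeats the simulation with fresh coefficients and
noises, summarizes each ordered module pair by the mean causality over its
block of the estimate matrix, and compares those block means against a
matched null — the same system regenerated with the latent cross-coupling
removed (b = 0) — with a one-sided Wilcoxon signed-rank test, Bonferroni
corrected over the 30 ordered module pairs.

The module also builds synthetic 4-D "voxel grid" volumes with contiguous
planted modules for exercising the volumetric pipeline without any real
acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import nibabel as nib
import numpy as np
from scipy import stats

from .community import build_hier_partition, correlation_matrix, pcgc_t_matrix
from .deconvolve import canonical_hrf
from .gc import GCMatrix, pairwise_gc_matrix
from .infoselect import pcgc_d_matrix
from .io import LabelVolume, TimeSeriesSet, VolumeMask

N_MODULES = 6
METHODS = ("pairwise", "pcgc_d", "pcgc_t")


@dataclass
class BenchmarkSpec:
    """Parameters of the modular AR validation system."""

    k: int = 20
    t_points: int = 5000
    reps: int = 100
    coeff_mean: float = 0.3
    coeff_var: float = 0.3
    ar_self: float = 0.5
    ar_cross: float = 0.5
    alpha: float = 0.05
    n_d: int = 10
    louvain_restarts: int = 10
    burn_in: int = 200
    module3_lag_coupled: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.t_points < 100:
            raise ValueError("t_points must be >= 100")
        if self.coeff_var <= 0:
            raise ValueError("coeff_var must be positive")
        if abs(self.ar_self) >= 1:
            raise ValueError(
                f"unstable AR self-coupling |{self.ar_self}| >= 1"
            )

    @property
    def n_vars(self) -> int:
        return N_MODULES * self.k


@dataclass
class ModuleDecision:
    """6 x 6 module-level decision matrix (diagonal ignored)."""

    decisions: np.ndarray
    statistic: np.ndarray
    p_corrected: np.ndarray

    def __post_init__(self) -> None:
        self.decisions = np.asarray(self.decisions, dtype=bool)
        np.fill_diagonal(self.decisions, False)

    def links(self) -> list[tuple[int, int]]:
        return [tuple(ij) for ij in np.argwhere(self.decisions)]


def ground_truth() -> np.ndarray:
    """Module-level truth: only Module 1 -> Module 2."""
    truth = np.zeros((N_MODULES, N_MODULES), dtype=bool)
    truth[0, 1] = True
    return truth


def module_labels(k: int) -> np.ndarray:
    return np.repeat(np.arange(N_MODULES), k)


def generate_benchmark(
    spec: BenchmarkSpec, rng: np.random.Generator | None = None
) -> tuple[TimeSeriesSet, np.ndarray]:
    """One realization of the 6k-variable system + the truth matrix."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    t_total = spec.t_points + spec.burn_in + 1
    a, b = spec.ar_self, spec.ar_cross
    eps = rng.standard_normal((t_total, 2))
    x1 = np.zeros(t_total)
    x2 = np.zeros(t_total)
    for t in range(1, t_total):
        x1[t] = a * x1[t - 1] + eps[t, 0]
        x2[t] = a * x2[t - 1] + b * x1[t - 1] + eps[t, 1]
    lo = spec.burn_in + 1
    m3 = (
        x1[lo - 1 : t_total - 1]
        if spec.module3_lag_coupled
        else rng.standard_normal(spec.t_points)
    )
    latents = np.column_stack(
        [
            x1[lo:],  # Module 1 carrier
            x2[lo:],  # Module 2 carrier
            m3,       # Module 3
            rng.standard_normal(spec.t_points),  # Module 4
            rng.standard_normal(spec.t_points),  # Module 5
        ]
    )
    c = rng.normal(spec.coeff_mean, np.sqrt(spec.coeff_var), size=5 * spec.k)
    data = np.empty((spec.t_points, spec.n_vars))
    for m in range(5):
        block = slice(m * spec.k, (m + 1) * spec.k)
        coeffs = c[block]
        data[:, block] = latents[:, [m]] * coeffs[None, :] + rng.standard_normal(
            (spec.t_points, spec.k)
        )
    data[:, 5 * spec.k :] = rng.standard_normal((spec.t_points, spec.k))
    labels = [
        f"m{m + 1}_{i + 1}" for m in range(N_MODULES) for i in range(spec.k)
    ]
    ts = TimeSeriesSet(
        data=data, dt=1.0, labels=labels, meta={"modules": module_labels(spec.k)}
    )
    return ts, ground_truth()


def block_means(matrix: np.ndarray, k: int) -> np.ndarray:
    """6 x 6 means of the off-diagonal-module blocks of a 6k x 6k matrix."""
    out = np.zeros((N_MODULES, N_MODULES))
    for a in range(N_MODULES):
        for b in range(N_MODULES):
            blk = matrix[a * k : (a + 1) * k, b * k : (b + 1) * k]
            if a == b:
                mask = ~np.eye(k, dtype=bool)
                out[a, b] = blk[mask].mean()
            else:
                out[a, b] = blk.mean()
    return out


def _method_matrix(ts: TimeSeriesSet, spec: BenchmarkSpec, method: str, seed: int) -> GCMatrix:
    if method == "pairwise":
        return pairwise_gc_matrix(ts, p=1)
    if method == "pcgc_d":
        return pcgc_d_matrix(ts, n_d=spec.n_d, p=1)
    if method == "pcgc_t":
        w = np.abs(correlation_matrix(ts))
        np.fill_diagonal(w, 0.0)
        hier = build_hier_partition(w, restarts=spec.louvain_restarts, seed=seed)
        return pcgc_t_matrix(ts, hier, p=1, mode="t")
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")


def score_decisions(
    decision: ModuleDecision | np.ndarray, truth: np.ndarray
) -> tuple[int, int, int]:
    """(TP, FP, FN) over off-diagonal module pairs."""
    dec = decision.decisions if isinstance(decision, ModuleDecision) else np.asarray(decision, bool)
    truth = np.asarray(truth, dtype=bool)
    if dec.shape != truth.shape:
        raise ValueError("shape mismatch")
    off = ~np.eye(dec.shape[0], dtype=bool)
    tp = int(np.sum(dec & truth & off))
    fp = int(np.sum(dec & ~truth & off))
    fn = int(np.sum(~dec & truth & off))
    return tp, fp, fn


def run_all_protocols(
    spec: BenchmarkSpec,
    methods: tuple[str, ...] = METHODS,
    seed: int | None = None,
) -> dict[str, ModuleDecision]:
    """Wilcoxon + FWE decision protocol for several estimators at once.

    Sharing the per-repetition data between the methods keeps the
    comparison paired in every sense: each repetition contributes one
    coupled and one matched decoupled (null) realization, analyzed by all
    requested estimators.
    """
    if spec.reps < 10:
        raise ValueError("need at least 10 repetitions for the signed-rank test")
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}; choose from {METHODS}")
    root = np.random.SeedSequence(spec.seed if seed is None else seed)
    alt_block = {m: np.zeros((spec.reps, N_MODULES, N_MODULES)) for m in methods}
    null_block = {m: np.zeros((spec.reps, N_MODULES, N_MODULES)) for m in methods}
    null_spec = replace(spec, ar_cross=0.0)
    for r, child in enumerate(root.spawn(spec.reps)):
        ss_alt, ss_null, ss_louv = child.spawn(3)
        ts_alt, _ = generate_benchmark(spec, np.random.default_rng(ss_alt))
        ts_null, _ = generate_benchmark(null_spec, np.random.default_rng(ss_null))
        louv_seed = int(ss_louv.generate_state(1)[0] % (2**31))
        for m in methods:
            alt_block[m][r] = block_means(
                _method_matrix(ts_alt, spec, m, louv_seed).gc, spec.k
            )
            null_block[m][r] = block_means(
                _method_matrix(ts_null, spec, m, louv_seed + 1).gc, spec.k
            )
    n_pairs = N_MODULES * (N_MODULES - 1)
    out: dict[str, ModuleDecision] = {}
    for m in methods:
        stat = np.zeros((N_MODULES, N_MODULES))
        pcorr = np.ones((N_MODULES, N_MODULES))
        dec = np.zeros((N_MODULES, N_MODULES), dtype=bool)
        for a in range(N_MODULES):
            for b in range(N_MODULES):
                if a == b:
                    continue
                diffs = alt_block[m][:, a, b] - null_block[m][:, a, b]
                if np.allclose(diffs, 0):
                    stat[a, b], pval = 0.0, 1.0
                else:
                    res = stats.wilcoxon(diffs, alternative="greater")
                    stat[a, b], pval = float(res.statistic), float(res.pvalue)
                pcorr[a, b] = min(1.0, pval * n_pairs)
                dec[a, b] = pcorr[a, b] < spec.alpha
        out[m] = ModuleDecision(decisions=dec, statistic=stat, p_corrected=pcorr)
    return out


def run_protocol(
    spec: BenchmarkSpec, method: str = "pcgc_t", seed: int | None = None
) -> ModuleDecision:
    """Single-method wrapper around :func:`run_all_protocols`."""
    return run_all_protocols(spec, methods=(method,), seed=seed)[method]


# ---------------------------------------------------------------------------
# synthetic voxel-grid fixtures


def generate_voxel_fixture(
    shape: tuple[int, int, int] = (8, 8, 8),
    n_modules: int = 6,
    t_points: int = 225,
    hrf_heterogeneity: bool = False,
    seed: int = 0,
    dt: float = 2.0,
    noise_sd: float = 0.5,
    coupling: float = 0.0,
    ar_self: float = 0.5,
) -> tuple[nib.Nifti1Image, VolumeMask, LabelVolume]:
    """Synthetic 4-D volume with spatially contiguous planted modules.

    Voxels inside a module share an AR(1) latent plus private noise, so
    spatially connected voxels display similar signals — the statistical
    structure the aggregated conditioning scheme assumes.  ``coupling``
    adds a one-step directed influence of module 1's latent onto module
    2's; ``hrf_heterogeneity`` convolves each voxel with a hemodynamic
    kernel whose peak latency varies across space.  Everything is
    deterministic given the seed.
    """
    if n_modules < 2:
        raise ValueError("need at least 2 modules")
    if any(s < 4 for s in shape):
        raise ValueError("grid must be at least 4 x 4 x 4")
    n_vox = int(np.prod(shape))
    if n_modules > n_vox:
        raise ValueError("more modules than voxels")
    rng = np.random.default_rng(seed)
    # contiguous modules: slabs along the first axis, split along the
    # second axis when n_modules exceeds the first-axis extent
    per_axis1 = int(np.ceil(n_modules / 2)) if n_modules > shape[0] else n_modules
    labels = np.zeros(shape, dtype=int)
    bounds = np.linspace(0, shape[0], per_axis1 + 1).astype(int)
    module = 1
    for s in range(per_axis1):
        slab = slice(bounds[s], bounds[s + 1])
        if module + 1 <= n_modules and n_modules > shape[0]:
            half = shape[1] // 2
            labels[slab, :half, :] = module
            labels[slab, half:, :] = module + 1
            module += 2
        else:
            labels[slab, :, :] = module
            module += 1
        if module > n_modules:
            break
    labels[labels == 0] = n_modules  # mop up any remainder rows

    burn = 100
    lat = np.zeros((t_points + burn, n_modules))
    eps = rng.standard_normal((t_points + burn, n_modules))
    for t in range(1, t_points + burn):
        lat[t] = ar_self * lat[t - 1] + eps[t]
        if coupling:
            lat[t, 1] += coupling * lat[t - 1, 0]
    lat = lat[burn:]

    data = np.empty(shape + (t_points,))
    flat_labels = labels.ravel(order="F")
    gains = rng.normal(1.0, 0.1, size=n_vox)
    series = (
        lat[:, flat_labels - 1] * gains[None, :]
        + noise_sd * rng.standard_normal((t_points, n_vox))
    )
    if hrf_heterogeneity:
        # peak latency ramps across the first axis: ~4 s to ~8 s
        ii = np.unravel_index(np.arange(n_vox), shape, order="F")[0]
        peaks = 4.0 + 4.0 * ii / max(shape[0] - 1, 1)
        for v in range(n_vox):
            h = canonical_hrf(dt, 24.0, peak_delay_s=peaks[v])
            series[:, v] = np.convolve(series[:, v], h)[:t_points]
    data = series.T.reshape(shape + (t_points,), order="F")
    affine = np.diag([3.0, 3.0, 3.0, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((3.0, 3.0, 3.0, dt))
    mask = VolumeMask(grid=np.ones(shape, dtype=bool), affine=affine)
    truth = LabelVolume(
        grid=labels,
        affine=affine,
        names={m: f"module{m}" for m in range(1, n_modules + 1)},
    )
    return img, mask, truth
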