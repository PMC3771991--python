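# Methods

## Causality core

For a target *y*, driver *x*, conditioning signals *Z* and lag order *p*,
both AR models are fitted by ordinary least squares on the identical
sample (rows *p … T−1*, so every lagged value exists), with an intercept
always included.  The causality index is the natural logarithm of the
ratio of restricted to unrestricted residual variance; because the models
are nested and share the sample, the index is nonnegative by construction
and we clip the ~1e-16 negatives that floating point produces.
Significance is the standard F-test,
`F = ((RSS_r − RSS_u)/p) / (RSS_u/(n_obs − k_u))` with `df1 = p` and
`df2 = n_obs − k_u`.  Values are reported in nats.

Rank-deficient designs raise an error that points at aggregation rather
than silently pseudo-inverting: unidentifiable coefficients are precisely
the failure mode the aggregated conditioning scheme exists to avoid.

All-pairs sweeps do not refit from raw data for every pair.  A single
Gram matrix of `[intercept | current values | lagged values]` is computed
once; each nested fit is then a small symmetric solve
(`RSS = <y,y> − c' G⁻¹ c` on the relevant index subset).  For aggregated
conditioning the aggregate columns are membership-weighted means, so their
cross-products are block means of the same Gram matrix.  The per-pair
route and the Gram route agree to ~1e-12 and the tests assert it; lag
orders above 1 fall back to the per-pair route in the aggregated sweep.

## Conditioning-set selection (PCGC^d)

Mutual information is the Gaussian closed form on sample covariances.
For lag order 1 a variable's state is its current value; for higher
orders its *p* most recent values form the state block.  The greedy
ranking maximizes the joint MI of the chosen set plus one candidate with
the driver; the implementation carries growing Cholesky factors so each
step is one triangular solve against all candidates.  Ties break on the
lowest column index for determinism.  Incremental gains are nonnegative
by the monotonicity of MI and the per-driver curve is exported for
inspection; the knee (maximum perpendicular distance between the
cumulative curve anchored at the origin and its end-to-end chord) gives a
stopping point when a fixed n_d is not imposed.  Default n_d = 10.

Each driver's ranking is computed one entry longer than n_d, and the
conditioning set of a pair is the first n_d ranked variables after the
target is excluded.  Every pair is therefore conditioned on exactly n_d
signals, and at n_d = N−2 the estimator coincides with the fully
conditioned one — a useful exact identity for testing.

## Community-aggregated conditioning (PCGC^t / PCGC^ti)

The partition comes from the Louvain algorithm on the absolute Pearson
correlation matrix (negative weights are controversial in modularity
optimisation, so magnitudes of the — group-averaged, when several
subjects are given — matrix are used, diagonal zeroed).  Louvain is
stochastic: it is restarted with fresh seeds and the assignment with the
highest Newman modularity Q is kept, Q being recomputed by our own
implementation so the reported value is exactly the returned partition's.
Each top-level system is then re-partitioned the same way to give
subsystems; singletons and weightless subgraphs become their own
subsystem.  The reference restart count for a production analysis is
10^4; the bundled tests and the benchmark protocol use 10–100 restarts,
which is ample for the planted structures they must recover.

For a driver, the conditioning set holds the mean signal of every
subsystem of the driver's own system (fine resolution where redundancy
with the driver is highest) and the mean signal of every other system
(coarse).  Mode `t` removes the driver from its subsystem before
averaging; mode `ti` leaves it in, which saves re-aggregating per driver
and changes values only marginally because one signal barely moves a
large group mean — the two modes' values correlate above 0.99 on the
synthetic voxel grid, mirroring their near-identity on real recordings.
An aggregate whose members are all already in the regression (member set
⊆ {driver, target}) is dropped; it is an exact linear combination of
modelled columns and would make the design singular.  The target always
stays inside its aggregate: its own past is modelled separately, and
diluting a group mean by one member is negligible at aggregate sizes of
interest.

Regressing on a group mean is identical to constraining the group's
members to share one AR coefficient (verified against constrained least
squares in the tests), which is the formal sense in which aggregation
fights multicollinearity while retaining all members' information.

## Preprocessing

Frame-wise displacement is the Power form: the sum of absolute backward
differences of the six rigid-body parameters, rotations converted to arc
length on a 50 mm sphere (configurable).  Frames with FD above 0.5 mm are
replaced by linear interpolation between the nearest clean frames
(boundary frames copy the nearest clean value); the operation is
idempotent.  Nuisance regression removes an intercept plus the supplied
confounds by OLS and refuses rank-deficient designs, naming the collinear
columns.  Band-pass filtering detrends linearly, then applies a
second-order-per-pass Butterworth forward and backward (zero phase —
phase distortion would corrupt the temporal-precedence structure GC
measures).  Default band 0.01–0.08 Hz.  Order of operations: scrub →
nuisance → detrend + filter.  Whether interpolated frames should be
excluded from the nuisance fit is genuinely open; they are kept, which is
conservative for short recordings, and the scrub threshold, radius, band
and filter order are all configuration.

## Blind deconvolution

The model: resting-state BOLD is a sparse train of spontaneous point
events convolved with a voxel-specific HRF plus noise.  Events are
detected as local maxima of the standardized signal above a threshold
(default 1.0 SD — "large amplitude" has no canonical number, and the
threshold is configuration).  Detected peaks trail their events by
roughly the HRF peak latency, so the chain shifts peak times back by the
canonical kernel's peak (the canonical double-gamma uses the SPM
parametrisation: response delay 6 s, undershoot 16 s, ratio 6, duration
32 s, unit peak).  All shifted onsets enter one joint design — the event
train convolved with the canonical kernel and its temporal derivative —
and the least-squares coefficients give the voxel's kernel; the
derivative term absorbs sub-sample voxel-specific timing.  The
pseudo-neural signal is the Wiener inverse
`X(f)·conj(H(f)) / (|H(f)|² + λ)`, with λ defaulting to the mean power of
the upper third of the spectrum (a noise-floor estimate; Wiener
regularisation has no canonical value for this signal class).

Known limitation: with a fixed (non-searched) event-to-onset lag, latency
differences are corrected only up to about one sampling interval; a voxel
whose HRF peaks several TRs later than the canonical kernel keeps an
integer-sample offset in its recovered train.  At TR = 2 s and the 4–8 s
latency range observed in cortex this is sufficient to align voxels to
within one TR, which the tests assert, and is what removes the bulk of
the spurious causality that heterogeneous hemodynamics inject: in the
heterogeneous-HRF simulation the tests run, the deconvolved pipeline
produces strictly fewer spurious significant links than the raw one.

## Simulation benchmark

Two AR(1) latents with one-way coupling (self-coupling 0.5, cross 0.5;
the printed source of the original construction survives only in part, so
these are package defaults chosen for stability and unambiguous one-way
coupling) drive Modules 1 and 2 of the 6k-variable system; Modules 3–5
are equal-time groups on independent white latents and Module 6 is pure
noise.  Mixing coefficients are i.i.d. N(0.3, var 0.3), observation noise
unit variance, 5000 points after burn-in.  Module-level ground truth:
only Module 1 → Module 2.

An alternative reading of the (redacted) Module 3 construction rides it
on the first latent delayed one step (`module3_lag_coupled`).  We measured
its consequence: Module 3's variables then genuinely predict Module 2's
future beyond any conditioning set — a second true link that every
correct conditioned estimator flags.  Because the benchmark's point is a
single planted link, the independent-latent construction is the default
and the lag-coupled one is a documented variant.

Decision protocol: per repetition the system is regenerated with fresh
coefficients and noises together with a *matched null* — the identical
construction with the latent cross-coupling set to zero.  Each ordered
module pair is summarised by the mean causality over its block of the
estimate matrix; the per-repetition alternative-minus-null differences go
into a one-sided Wilcoxon signed-rank test, Bonferroni-corrected over the
30 ordered pairs at level 0.05.  A zero-mean-coefficient null was
considered and rejected: causality depends on coefficient magnitudes, not
signs, so such a null retains the planted coupling and cannot separate
signal from reference.  The package default is 20 repetitions (the
reference protocol uses 100); at 20 the signed-rank test needs near-total
consistency of the paired differences to reject, which is the intended
conservatism at desk scale.

PCGC^t inside the protocol re-detects the community structure of every
realization (10 Louvain restarts) and uses mode `t` with the global
partition; PCGC^d uses n_d = 10; pairwise uses the empty conditioning
set.  All estimators see identical data, so the method comparison is
paired throughout.

The voxel-grid generator plants contiguous modules (axis-aligned slabs)
sharing AR(1) latents plus voxel noise (noise SD 0.5, voxel gains
N(1, 0.1²), TR 2 s, 225 volumes by default — the acquisition geometry the
temporal defaults elsewhere assume), with optional module-1 → module-2
latent coupling and optional spatially ramped HRF latencies (4–8 s).  It
emulates the local-redundancy structure the aggregated scheme assumes and
none of the anatomy, physiological noise, or scanner artefacts of real
data; passing tests therefore validate the estimators' statistical
behaviour, not their robustness to acquisition effects.

One consequence of the noisy-copy construction worth knowing when using
the seed mapper on it: a strict subset of a module is fully redundant
with its own community aggregate, so its unique contribution is (correctly)
conditioned away; seed regions should be whole modules there.  Real
voxels carry idiosyncratic signal and do not behave this way.

## Network statistics

Adjacency convention: row *i*, column *j* means *i* causes *j*; incoming
degree is the column sum.  Thresholding keeps weights strictly above the
cut (default 0.3), binary or weighted.  Betweenness uses edge length =
1/weight (strong links are short) and counts shortest-path pair fractions
without normalisation.  The directed clustering coefficient counts
existing directed links among a node's out- (or in-) neighbours over
k(k−1), on the binarized graph; this per-direction neighbourhood reading
is one of several directed generalisations and is chosen to pair with the
separate in/out analyses.  Cross-subject comparison divides each node's
value by the subject's across-node mean before averaging over subjects; a
node is a hub for a measure when its normalized value strictly exceeds
mean + SD (sample SD over the supplied nodes), and a hub overall at score
≥ 2 of 3.  Cluster-extent filtering removes connected components under 27
voxels at 26-connectivity (the full 3×3×3 neighbourhood; 6-connectivity
is available).

## Numerical and reproducibility choices

Every stochastic routine takes an explicit seed, child seeds are spawned
via `numpy.random.SeedSequence`, and identical configuration + seed gives
bit-identical outputs.  Tolerances in the tests: exact identities at
1e-10–1e-12, estimator-vs-closed-form checks at their sampling noise
(e.g. Gaussian MI compared to −½ln(1−ρ²) as a five-draw mean at T = 10⁴,
because a single draw's sampling noise at ρ = 0.8 is of the same order as
the 0.01-nat band).  Problem sizes in the test and acceptance runs —
k = 20 with 20 repetitions for the benchmark, 512-voxel grids, 225-point
series — are the package's chosen desk-scale study conditions.
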