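# Methods

This note records the models, numerical conventions and design decisions
behind `dynfc`, in the order of the pipeline.

## Discrete RID-Rihaczek distribution

All four domains (time, frequency, Doppler θ, lag τ) are L-point uniform
DFT grids.  The instantaneous autocorrelation uses the asymmetric circular
lag `R[n,l] = x[n] x*[(n−l) mod L]`:

* the DFT of `R` over n is the ambiguity function, so `A[0,0]` equals the
  signal energy exactly;
* the DFT of `R` over l is exactly the Rihaczek product form
  `(1/2π) x[n] X*[k] e^{−j2πnk/L}`.

The asymmetric lag *absorbs* the Rihaczek half-shift kernel `e^{jθτ/2}`, so
the σ = ∞ path is an exact identity rather than an approximation — this is
the oracle the test suite checks to 1e−8.  The Choi-Williams kernel is
evaluated as `exp(−(θτ)²/σ)` with θ in rad/sample and τ in samples (both
signed, fftfreq layout); the default σ = 0.01 suppresses cross-terms
strongly.  Real inputs are converted to their analytic form
(`scipy.signal.hilbert`) before the transform, so phase is single-sided and
the returned frequency axis spans [0, fs/2].

Where cross-terms appear. For a two-tone signal the Rihaczek cross-terms do
*not* sit at the mid-frequency: the product form confines energy to the
auto columns, where interference shows up as temporal beating of |C| (and
of the phase).  The kernel removes that beating — on the two-tone test
fixture the temporal standard deviation of |C| at an auto column drops from
7.5 (σ = ∞) to 0.23 (σ = 0.01) — and off-axis ambiguity-domain energy is
monotonically non-increasing as σ decreases, because the kernel is
pointwise monotone in σ.

Phase is undefined at zeros of C; entries with `|C|` below a magnitude
floor (default 1e−12 × max|C|) are masked, and masked bins are excluded
from PLV sums with the trial count reduced per bin (strict mode errors
instead).

## PLV and graphs

PLV is `(1/K)|Σ_k e^{jΦ_k}|` over trials, with the pair phase difference
computed from unit phasors `(C_i/|C_i|)(C_j*/|C_j|)`.  For K independent
uniform phases the expected PLV is the Rayleigh floor `sqrt(π/(4K))` — the
effective noise level of every cross-trial locking estimate.

Band averaging is inclusive of both endpoint bins on the discrete frequency
grid (the theta band 4–8 Hz at 0.5 Hz resolution covers nine bins).  Graph
weights inherit the [0,1] range; diagonals are forced to zero.  Sample t
maps to milliseconds as `t0 + t/fs·1000` (0-based).

One arithmetic convention deserves note: published event-interval tables
printed in integer milliseconds partition the epoch's samples exactly when
the 256 samples are treated as *centres of equal-width bins* spanning the
2 s epoch (`t = −1000 + (k+½)·7.8125 ms`).  `events.interval_sample_counts`
implements that convention; it reproduces per-interval graph counts
115/13/15/18/26/69 for the six printed intervals.

## Change detection

With a trailing window of δ distances (default δ = round(0.025·T), i.e. 6
for T = 256 — "2.5% of the epoch's sample count"), transition t is flagged
when `|D_t − μ_t| ≥ max(2σ_t, floor)`.  The max-form floor (default 1e−12)
replaces a bare `σ_t > 0` guard: an exactly constant history produces no
flags, while a genuine step on a constant history (where σ_t = 0) is still
detected.  The window uses the population standard deviation and does not
reset at detected boundaries; no detection is attempted for the first δ
transitions, so the first interval always starts at the first graph.

False-alarm calibration.  The rule is scale-free: on an i.i.d. Gaussian
series the flag probability is exactly
`P(|t_{δ−1}| ≥ 2·sqrt(δ−1)/sqrt(δ+1))` — 0.152 at δ = 6, 0.048 at δ = 200,
approaching the nominal `P(|Z| ≥ 2) = 0.0455` only for long windows.  Two
practical consequences: (i) the calibration test is run at δ = 200 where
the normal approximation holds; (ii) on noisy stationary data the default
window *will* flag a few percent of transitions, so segmentation of real
data relies on the distance series being temporally smooth (as
subject-averaged sequences are), or on an explicit `sigma_floor` expressing
the smallest change worth calling an event.  The synthetic studies use
`sigma_floor = 0.05` (half the smallest planted jump) and `edge_guard = 2`
(the analytic-signal conversion corrupts phase estimates at the last
samples of the epoch, which otherwise produces a spurious final boundary).

## Key graphs

Graphs are vectorized by column-major stacking of the strict upper triangle
(d = N(N−1)/2).  Eigenpairs of the interval covariance are computed by thin
SVD of the centered M × d data matrix — mathematically identical to the
dense d × d eigendecomposition (kept as a test oracle) and far cheaper when
d ≫ M.  L is the smallest count of leading eigenvalues whose cumulative
share reaches ξ = 90%; eigenvalues below 1e−12 of the largest are clamped
to zero, and a covariance whose leading eigenvalue is at round-off level
relative to the data scale is treated as zero (degenerate interval → the
key graph is the plain interval mean, as for M = 1).

Projection is applied to the raw, *uncentered* vectors (`p_i = V_L^T z_i`),
as the summarization is defined; the centered variant is available via
`centered=True` and then the key graph equals the interval mean exactly.
By linearity the uncentered key vector is `V_L V_L^T z̄` — the projection of
the interval-mean graph onto the high-variance subspace.  Two properties
follow: reconstruction error equals the discarded eigenvalue mass
`(M−1)·Σ_{i>L} λ_i`, and re-summarizing the reconstructed set at full
retention returns the same key graph.  Reconstructed weights may leave
[0,1]; they are reported raw.  Eigenvector signs are fixed
(largest-magnitude component positive) for output determinism only — the
key graph itself is sign-invariant.

Note that the projection keeps *variance* directions: edges that are strong
but constant within an interval are attenuated unless the interval's
variance is carried by the same edges.  This is intended (the summary
highlights dynamic interactions), and it constrains what synthetic data
must look like for the key graph to recover planted structure (below).

## Surrogate significance

Two reshuffling schemes generate surrogate time-varying networks, both
conserving each slice's weight multiset:

* `per_slice` (default): the strict-upper-triangle weights are permuted
  independently at every time point;
* `fixed_permutation`: one edge-*position* permutation per surrogate is
  applied to all slices, preserving each edge's temporal profile.

Empirical one-sided p-values use the plus-one correction
`p = (1 + #{null ≥ obs})/(1 + n_null)` and are never zero; with S
surrogates the attainable minimum is 1/(1+S) per edge, or 1/(1+S·d) pooled
across the d edge positions (the default, and the only way 2000 surrogates
can resolve P < 0.001).  A tolerance of 1e−9 (relative) treats numerically
tied null values as ties.  No multiple-testing correction is applied; raw
flagged-edge counts are reported.

Calibration caveat (measured, not hypothetical): under a realistic null in
which the graph sequence is temporally correlated — which PLV sequences
always are — `per_slice` reshuffling whitens the sequence, so surrogate key
graphs concentrate near the mean while the original key graph disperses
into its variance subspace; the result is anticonservative (≈ 13% of edges
flagged at nominal 1% on no-structure synthetic data).  The
`fixed_permutation` scheme preserves the temporal structure and is exact by
permutation symmetry; the null-calibration acceptance test uses it.  For
real data this argues for `fixed_permutation`, or for interpreting
`per_slice` p-values only comparatively.

Node-strength comparisons use Welch's unequal-variance t-test
(Welch–Satterthwaite degrees of freedom, two-sided, α = 0.05) on the
node's N−1 edge weights from each key graph.

## Synthetic data: signal model and rationale

The generator plants coupling structure in *stochastic* narrowband
oscillations.  Per (trial, regime, cluster) a carrier at the regime's
frequency carries a random-walk phase (diffusion 0.1 rad/sample, i.e. a
coherence time of a few hundred ms — theta-burst-like); channels of a
cluster share the walk up to a per-(trial, channel) jitter offset
(sd 0.1 rad), and uncoupled channels carry independent walks.  Three
features are deliberate and were forced by properties of the estimator
chain (each was verified empirically during design):

1. **Stochastic phases, not deterministic tones.**  The Rihaczek phase
   couples x(t) with the global spectral phase X(ω).  For a deterministic
   tone these determine each other, so per-trial random offsets cancel out
   of the pairwise phase difference and PLV saturates near 1 *regardless of
   coupling*.  Phase diffusion breaks the degeneracy.
2. **One carrier per regime (4.5 / 6 / 7.5 Hz, inside theta).**  A channel
   whose coupling partners change during the epoch inherits a trial-random
   global spectral phase at any bin where several regimes' energy mixes,
   which destroys its measured within-regime locking.  Distinct carriers
   make regimes spectrally separable, so each pair's locking is read out at
   its own regime's bin.
3. **Within-interval synchrony modulation.**  The key-graph projection
   keeps variance directions, so planted edges must carry the interval's
   variance (as waxing-and-waning coupling does in real recordings).  Two
   slow processes provide it: a per-channel phase wobble whose depth rises
   to 2.0 rad mid-regime and vanishes at boundaries, and a global common
   component (volume-conduction-like) mixed in with peak weight 0.45
   mid-regime.  Both profiles are zero at regime transitions, so boundary
   jumps stay sharp.

The default layout is an A-B-A event design — two baseline assemblies
(channel halves); the first splits into two sub-assemblies during the
middle regime and re-forms — so every planted pair is coupled during at
least two regimes and identifiable at the band-average level.  Additive
white noise sd is 0.05 relative to unit carrier amplitude.

Analysis configuration for synthetic studies
(`dynfc.study_analysis_config()`): plain Rihaczek phase (σ = ∞ — the
planted signals are monocomponent at any instant, so there are no
cross-terms to suppress, and unfiltered phase has the sharpest time
localization), band 4.5–7.5 Hz (the span of the planted carriers),
detection floor 0.05, edge guard 2.  Under these conditions (N = 16,
K = 50, fs = 128 Hz, T = 256) planted boundaries are recovered within ±1
sample and key-graph rank agreement with the planted clusters is
0.95–1.0 across seeds (occasionally 0.94 at an adverse seed).

What the generator does *not* emulate: volume conduction beyond a single
global common component, realistic electrode geometry or source mixing,
1/f background spectra, artifacts, or inter-subject variability.  Passing
the planted-recovery tests therefore demonstrates correctness of the
estimator chain under known ground truth, not performance on real EEG.

## Sizes used in tests and the acceptance script

Unit fixtures use L ≤ 64 signals and N ≤ 10 graphs.  The planted-recovery
study runs one full dataset (16 channels × 50 trials × 256 samples,
~120 000 pairwise PLV spectra); the null calibration runs 20 no-structure
datasets (16 channels × 30 trials) with 500 surrogates each — surrogate
counts below the 2000 default keep the studies at a few minutes on one CPU
while leaving the pooled p-value resolution (1/(1+S·d) ≈ 1.7e−5) far below
the levels tested.
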