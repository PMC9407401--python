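# Methods

This note documents the models, estimators, numerical choices and
limitations of `boldcomplexity`, in the spirit of a package methods
appendix. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is quoted from external
results.

## Signal model

A regional BOLD time series is modelled as approximately monofractal:
fractional Gaussian noise (fGn) with Hurst exponent H ∈ (0, 1) and
autocovariance

    γ(k) = ½ (|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H}),

whose integrated path is fractional Brownian motion (fBm) with power
spectrum P(f) ∝ f^(−β), β = 2H + 1. H = 0.5 is memoryless; cortical BOLD
typically spans H ≈ 0.5–0.9. Complexity is summarised three ways — H, β,
and the multiscale-entropy complexity index — because they weight temporal
structure differently while agreeing on the order–disorder axis.

## Estimators

**DFA Hurst.** The mean-centred series is integrated; in non-overlapping
windows of 15 log-spaced sizes s ∈ [10, n/4] an order-1 polynomial is
removed; H is the least-squares slope of log₁₀ F(s) vs log₁₀ s, where
F(s) is the pooled RMS residual. Defaults (order 1, 15 sizes, forward
non-overlapping pass) are conventional choices; the suite verifies
calibration at H = 0.5 (mean over 200 white-noise series within ±0.03) and
recovery of H ∈ {0.55…0.85} within ±0.05. Inputs that are exactly a
polynomial of degree ≤ the detrend order (constants, pure ramps at order 1)
are rejected as degenerate: they have no stochastic fluctuation, so no
scaling exponent exists. Window fits use a polynomial basis on t rescaled
to [−1, 1], which keeps the projections well conditioned at every window
size and lets all windows (and all columns, in the batched variant used
for surrogate ensembles) be solved in one projection per size.

**Spectral exponent.** Welch PSD with a Hann window, segment length
min(n, 128), 50% overlap, and per-segment *linear* detrending; β is the
negated slope of a base-10 log-log least-squares fit restricted to
0.01–0.2 Hz (zero-power bins dropped; at least 5 bins required). Linear
rather than mean-only segment detrending is deliberate: signals with
β ≳ 2 are effectively nonstationary over a 128-sample segment, and
mean-only detrending inflates the fitted slope by up to ≈ +0.3 at β ≈ 2.7,
breaking the β = 2H + 1 identity; with linear detrending the identity
holds within ±0.1 across the simulated H range and coloured-noise round
trips (β ∈ {0…2}) recover the generating exponent within ±0.15.

**Sample entropy.** SampEn(m, r) = −ln(A/B), counting unordered template
pairs of lengths m+1 (A) and m (B) over the first n−m start points,
Chebyshev distance strictly < r, self-pairs excluded. Defaults m = 2,
r = 0.15 × SD of the original series. When either count is zero the value
is *undefined* and carried as a NaN marker, never silently dropped. The
O(n²) pair count is a numba-compiled kernel; tests pin it to an exhaustive
pure-python oracle exactly on short series and to the closed form
−ln(2Φ(r/σ√2) − 1) for i.i.d. Gaussian input.

**Multiscale entropy and complexity index.** The series is coarse-grained
by non-overlapping block means at scales τ = 1…10 (default), with r fixed
from the *original* series SD across all scales — the standard convention,
which makes white-noise entropy fall with τ (the fixed r grows relative to
the shrinking coarse-grained SD) while 1/f-like signals stay flat. A scale
whose coarse series is shorter than 10·(m+1) samples is undefined. The
complexity index is the trapezoidal area over scale index restricted to
the *leading* run of defined scales (undefined if fewer than two). Ten
scales fit runs of 263–399 volumes while keeping every scale defined; at
these lengths the index separates pink from white noise reliably (the
white/pink area ordering holds in ≥95% of paired draws at n = 4096), but
note the curves cross only around τ ≈ 4 — with 5 or fewer scales the
ordering inverts, so shrinking the scale range materially changes the
statistic.

## Task GLM

Each trial (or condition) is a boxcar sampled on the TR grid, convolved
with a canonical double-gamma HRF (response peak 6 s, undershoot peak
16 s, unit dispersions, peak:undershoot 6, 32 s support, unit peak
amplitude; gamma shapes are delay/dispersion + 1 so the mode sits exactly
at the stated delay). The design adds an intercept and, by default, a
linear drift column; trials extending past the run are truncated with a
warning. Removal is plain column-wise OLS (no prewhitening); collinear
columns are dropped via pivoted QR with a warning. On synthetic task data
the regression suppresses the task-frequency spectral peak while changing
the residual β̂ by < 0.15 relative to the same noise realisation without a
task — the regression removes the evoked component, not the scale-free
background.

## Graph surrogates

The connectome's symmetric normalised Laplacian L = I − D^{−1/2} A
D^{−1/2} (combinatorial variant available behind a flag) is
eigendecomposed into orthonormal spatial harmonics, ordered by ascending
eigenvalue, each sign-fixed so its largest-magnitude entry is positive,
with lexicographic ordering inside numerically degenerate eigenvalue
groups — making the basis deterministic for a given matrix. A surrogate is
X ↦ X · U diag(s) Uᵀ with s a ±1 vector (harmonic 1 pinned to +1; one
vector per surrogate, constant over time — per-frame resampling would
destroy temporal correlation). The operator is orthogonal, symmetric and
involutory, so each surrogate exactly preserves X·Xᵀ (all second-order
temporal statistics) and the per-harmonic spectral magnitudes, while
randomising where on the graph the dynamics live. Ensembles are seeded per
surrogate from (master_seed, index), so any single surrogate is
regenerable in isolation. Dense eigendecomposition only: intended for
parcellations up to ~1000 regions.

A subtlety worth recording: if every region has identical variance and the
cross-regional covariance is produced purely by a function of the graph
(as with heat-kernel smoothing of unit-variance noise), the covariance is
diagonal in the harmonic basis and sign flips leave functional
connectivity unchanged *in expectation*. Randomisation of FC is therefore
only observable when the covariance has harmonic-off-diagonal structure —
which real data always has, through regional variance heterogeneity. The
synthetic generator includes that heterogeneity (below), and the FC
randomisation check is formulated as a per-entry two-sided sign test
(original vs 100 surrogate FC values, α = 0.01): on structure-coupled data
a large fraction of entries reject, against a ~1% rate were FC preserved.
The *mean off-diagonal FC magnitude* is, by the same argument, not a
reliable contrast — sign flips scatter entries around the
harmonic-diagonal projection, adding magnitude where the preserved part is
small — and is not used as a test.

## Group inference

Subject-level: one-sided empirical p = (1 + #{null ≥ observed}) /
(1 + n_surr) — the add-one form guarantees validity, and with 100
surrogates at α_subj = 0.01 a detection requires the observed statistic to
exceed every surrogate. Undefined surrogate statistics count against
significance. Group level: the number of detections per region is compared
with the smallest n whose exact Binomial(n_subj, α_subj) upper-tail
probability is ≤ α_group / n_comparisons (Bonferroni; tail by exact pmf
summation). The thresholded statistic defaults to the complexity index and
can be switched to H or β; for contrasts that are *defined* on H (as in
the synthetic power study) the H statistic is the direct choice — at 399
volumes the complexity index barely separates H = 0.6 from 0.8 (ΔCI ≈ 0.5
against a between-draw SD of 1–3), while DFA separates them cleanly.

Per-network summaries report the percentage of suprathreshold regions
normalised by each network's size by default; a whole-brain denominator is
available since both readings of "normalised by the number of ROIs" are
defensible.

## Task-specificity classifier

For each unordered pair of runs, subjects are observations and per-region
complexity maps are features. Loss is the stratified 5-fold
cross-validated misclassification fraction of an SVM with an inner 3-fold
grid search (nested CV keeps the outer estimate unbiased) over the box
constraint C ∈ {0.1, 1, 10, 100} and, for the RBF kernel, kernel scale
γ ∈ {0.1, 1, 10} × a median heuristic 1/median(pairwise squared distance).
Features are standardised inside each training fold; the median heuristic
is computed once on the pooled, standardised pair data — it is a length
scale, not a fitted parameter, but it *must* be computed on the scale the
kernel actually sees (on raw Hurst features, whose SD is ~0.1, it is two
orders of magnitude off and the grid never reaches useful γ). Both RBF and
linear kernels are exposed as first-class options. Losses from shuffled
stratified folds are deterministic per seed but not exactly symmetric
under swapping the two class blocks (fold membership depends on block
order); symmetry holds statistically and the loss matrix evaluates each
pair once.

## Synthetic data generator

The generator emulates the study conditions this pipeline targets: runs of
263–399 volumes at TR = 0.72 s (defaults n_time = 399, TR = 0.72),
regional Hurst exponents spanning 0.5–0.9 (default map: linear ramp across
regions), 100-subject populations, per-subject H jitter (subject_sd,
default 0.05, clipped to (0.05, 0.95)), regional amplitude heterogeneity
(lognormal with sigma roi_amplitude_sd = 0.5 — regional BOLD variance
varies severalfold in real data, and without it surrogate FC randomisation
would be invisible, see above), structure–function coupling by per-frame
heat-kernel smoothing exp(−t·L_norm) with t = coupling_strength, and
optional task blocks (HRF-convolved boxcars added to designated regions,
default all). Columns are standardised last. fGn is sampled *exactly* by
circulant embedding of the autocovariance (spectral synthesis is only a
guarded fallback); fBm is its zero-anchored cumulative sum; coloured noise
is spectral synthesis with coefficients scaled by f^(−β/2).

Connectomes are distance-decay random graphs on uniform points in the unit
cube (decay length 0.3 — an arbitrary but reported default — with
lognormal edge noise), thresholded to a target density and re-bridged to
connectedness if needed. Coupling strength has no published target value;
t = 0.5–1.0 produces FC–structure Spearman correlations of ~0.5–0.8,
which is the regime the surrogate tests need.

Seeding: `default_rng` over composite integer seeds; subject i of a
population uses (master, i); within a subject, (seed, 0) draws the H
jitter, (seed, 2) the amplitudes, and (seed, 1, roi) each region's fGn —
every component is regenerable in isolation.

What the generator does **not** emulate: physiological noise (cardiac,
respiratory), motion artefacts, spatial smoothing of preprocessing,
hemodynamic nonlinearity, multifractality, and empirically realistic
connectome topology. Tests passing on this generator demonstrate that the
estimators and inference machinery behave correctly under a known
scale-free, structure-coupled model — not that real BOLD satisfies that
model.

## Study sizes used by the test suite

The statistical suite runs at deliberately chosen problem sizes:
estimator calibration at n = 4096 with 100–200 seeds; surrogate contracts
on a 30-region, 399-volume, 100-surrogate fixture; the end-to-end
detection study at 20 regions, 399 volumes, 50 surrogates, 100 subjects
for the power run (elevated region ΔH = 0.2) and 100 repetitions of
60-subject pure-null cohorts for false-positive control. With 50
surrogates the smallest attainable empirical p is 1/51 ≈ 0.0196, so the
subject-level α for those runs is 0.02 — detection still means "observed
exceeds every surrogate". The pure-null cohorts set subject_sd = 0: the
surrogate null hypothesis is "no spatial variation of scale-free
dynamics", and per-subject H jitter *is* such variation, so a jittered
cohort is not a null cohort (it measurably inflates subject-level
detection rates above α).

## Known limitations

* Monofractal model only; no multifractal spectrum estimation.
* DFA window policy is fixed (non-overlapping, forward pass); overlapping
  windows would reduce variance at extra cost.
* The complexity index depends on the chosen scale range (see above);
  comparisons are only meaningful at matched scales and r.
* The surrogate null is structured, not exact: it conditions on the graph
  and the per-harmonic spectra. Calibration was verified empirically under
  the generator's null; other data-generating processes may differ.
* Classifier losses at small n (tens of subjects) carry fold-level noise
  of a few percent; interpret single-pair differences accordingly.
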