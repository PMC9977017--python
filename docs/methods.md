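# Methods

This note records the models, estimators and numerical conventions behind
`physiomot`, the choices made where the design was genuinely open, and what
the synthetic experiments do and do not demonstrate.

## Signals and missingness

All signals are `(t, value)` series with strictly increasing timestamps;
missing data is represented by absent samples, never by NaN. The clock is
local seconds from midnight of day 1 and visits start at 00:00, which makes
the two rule-bearing intervals unambiguous: the nocturnal HRV window
22:00–10:00 (half-open, windows assigned by start time) and
midnight-to-midnight actigraphy days.

### SQI channel fusion

When up to four chest-patch channels cover the same window, the channel
with the highest signal-quality index wins (ties to the lowest channel id,
for determinism); its data is kept only if SQI is strictly greater than
0.75, otherwise the window becomes a gap. The bundled `simple_bsqi` is a
deliberately simplified beat-detector-agreement index: an
amplitude-threshold detector on a 5–15 Hz band-passed signal and a
permissive slope-energy detector are matched within ±150 ms, and the score
is matched / (n₁ + n₂ − matched). The slope-energy detector's low threshold
is intentional: on clean ECG only QRS complexes carry slope energy, while
broadband noise triggers it densely, which is what drives the agreement
down on bad signal. Fewer than 3 matched beats scores 0.

### Surrogate imputation

Gaps with inter-sample spacing > `th_g` (defaults: 60 s for 30-s grids,
300 s for raw RR; the threshold is a free parameter of the method) are
filled in ascending length order. Per gap: a fair coin picks the left or
right neighbourhood; a draw x_r ~ N(0,1) maps to a donor offset
|x_r|·g_l beyond the admissible boundary — left donors end at
t_b − g_l − offset, right donors start at t_e + offset — resampled up to
50 times (then the other side) until the donor window lies fully inside
sampled data with no internal spacing > `th_g`, including its edges, so a
splice can never create a fresh gap. Donor samples are copied into the gap
and per-sample noise 0.05·z, z ~ N(μ_S, σ_S²) is added, with μ_S, σ_S²
the pre-imputation series moments. Because earlier (shorter) gaps update
the series before later ones, filled segments can serve as donors.

Two consequences worth knowing. First, the noise term has mean 0.05·μ_S,
so for signals with a large mean (HR ≈ 80 bpm) imputed stretches are
shifted upward by ≈ 5% of the mean; distribution-recovery checks are
therefore run on centred signals. Second, donor timestamps are shifted
into the gap as-is; for uniform-grid signals the optional `align` parameter
rounds offsets down to a grid multiple so imputed samples stay on-grid
(used by the pipeline for the 30-s HR/DC/activity grids; residual
sub-threshold holes are closed by linear interpolation when the grid is
assembled).

### PCHIP hourly imputation

Hourly activity totals; empty interior hours are filled with
shape-preserving piecewise-cubic Hermite interpolation over the hour index
(no overshoot on monotone segments, exact on linear ramps); empty leading/
trailing hours take the nearest observed hour's value, since PCHIP is an
interior interpolant.

## HRV features

RR series are cleaned first: intervals outside [300, 2000] ms or changing
more than 20% from the previous accepted beat are dropped (toolbox-style
artifact handling). Windows are [k·30 s, k·30 s + 300 s); a window is valid
if its beats cover ≥ 80% of the window (inter-beat spans > 2 s do not count
as coverage). Windows need ≥ 30 beats to be scored.

The 24 metrics: nn_mean, nn_median, nn_mode (10-ms binning, ties to the
smaller value), nn_var, nn_skew, nn_kurt, nn_iqr, sdnn, rmssd, pnn50,
hr_mean; ULF/VLF/LF/HF band powers, LF/HF and total power from a
Lomb–Scargle periodogram on the irregular beat times (band edges 0.003 /
0.04 / 0.15 / 0.4 Hz; trapezoidal band integration on a grid that is finer
below 0.04 Hz); SampEn and ApEn (m = 2, r = 0.2·SD, one shared Chebyshev
distance matrix); PRSA AC/DC; DFA α1 (4–16 beats) and α2 (16–64 beats,
box sizes capped at n/4); SD1/SD2 from the Poincaré identities
SD1² = ½·var(Δrr), SD2² = 2·SDNN² − SD1². Variances use the n−1
denominator throughout.

**Deceleration capacity.** Anchors are beats whose RR lengthens by at most
5% relative to the previous beat; AC mirrors this for shortenings. The
phase-averaged response X(k) is combined as
DC = (X(0) + X(1) − X(−1) − X(−2)) / 4. Since only four phases enter, DC
equals the mean of the per-anchor quantity
(rr[a] + rr[a+1] − rr[a−1] − rr[a−2]) / 4; the 30-s DC grid slides a 300-s
window across 48 h in O(n) using a cumulative sum of these per-anchor
contributions (≥ 3 anchors per window, else the bin is missing). Whole-
series DC excludes anchors within L = 30 beats of the edges; inside 300-s
windows the exclusion shrinks to what the window supports, since a ±30-beat
exclusion would discard most anchors of a ~370-beat window.

Nocturnal aggregation takes the sample mean and variance of each metric
over all valid windows starting in [22:00, 10:00) across both nights —
48 features; fewer than two nocturnal windows flags the visit missing.

## Actigraphy features

Oakley-style counts: 0.25-Hz high-pass (removing gravity), per-second
maximum absolute deviation, 0.05 g deadband, sum of supra-threshold
per-second maxima per 30-s epoch; input must be sampled ≥ 20 Hz. Day
selection scans consecutive midnight-to-midnight pairs, scores each day by
its sampled hours (epoch count × epoch length), picks the pair with the
largest total (ties to the earliest), and rejects the visit if either
chosen day has under 12 h. IS/IV use the standard interdaily-stability and
intradaily-variability forms; L5/M10 are extremes of 5-h/10-h moving
averages over the 48 hourly values; "rest activity" is pinned as the
relative amplitude RA = (M10 − L5)/(M10 + L5), the standard summary
alongside IS/IV/L5/M10. The cosinor fit is linear least squares in
(1, cos ωt, sin ωt) with amplitude ≥ 0 and acrophase in [0, 24) hours; a
constant signal yields amplitude 0 with acrophase reported as 0 and a
degeneracy flag.

## Transfer entropy and the adaptive partition

All block lengths and lags are 1: the embedding is (y_i, y_{i−1}, x_{i−1}).
Each coordinate is rank-normalized to (r − 0.5)/n with average ranks for
ties, so repeated values collapse to an atom instead of simulating
dependence. The partition recursively splits cells at their midpoints into
2^d subcells when occupancy is ≥ 8·2^d and the χ²(2^d − 1) uniformity
statistic exceeds the α = 0.05 critical value; a split that fails to
separate the points (a pure atom) is never taken, which both handles
degenerate inputs and guarantees termination. The plug-in estimator sums
p̂·ln[n_cell·N(y′) / (N(y,y′)·N(y′,x′)) · N] over leaves with marginal
counts taken over each leaf's projected rank ranges; estimates are in nats
and may be slightly negative (tolerance −0.01) because the projected
marginals are not derived from a common coarsening. Rank-based embedding
makes the estimator exactly invariant under strictly monotone transforms
of either series.

Coarse-graining is non-overlapping averaging (trailing remainder dropped),
applied per signal before embedding; scales 1–10 on the 30-s grid span one
sample per 30 s to one per 5 min.

Against the closed-form Gaussian VAR(1) oracle (stationary covariance via
a discrete Lyapunov solve) the estimator's median at n = 10⁴ sits within
about 15% of truth for moderate coupling — a known mild negative bias of
partition-based plug-in estimators.

## Transition networks

Nodes are the occupied leaves of the 3-D partition of the coarse-grained
(HR, DC, Act) cloud; consecutive samples in different cells add an
undirected edge, same-cell transitions mark a self-loop. The first
partition split is unconditional (separability permitting): a pure
Darbellay–Vajda partition of independent signals is a single cell, which
would make every network metric vacuous on weakly dependent data; constant
signals still collapse to a single self-loop node because their rank atoms
cannot be separated.

Metrics: n_nodes; average degree (self-loops excluded); cyclomatic number
|E| − |V| + #components; 3-/4-cycle counts via tr(A³)/6 and
(tr(A⁴) − 2|E| − 2Σ deg(deg−1))/8, validated against exhaustive
enumeration; clust1 = LOOP3 / connected triples exactly as defined (no
factor 3; the conventional transitivity is 3× this); clust2 = mean local
clustering; radius on the largest connected component (eccentricity is
infinite across components); spectral radius, trace and energy = Σλ² on
the adjacency with diagonal ones for self-loop nodes — without self-loops
the trace of a simple symmetric adjacency is identically zero and the
trace feature would be vacuous. Note this "energy" (Σλ² = tr A²) is the
squared-eigenvalue sum, not the conventional graph energy Σ|λ|.

## Severity model

Labels: CGI-S ≤ 4 → low, > 4 → high. Feature families are tagged by column
prefix; the 15 combinations are enumerated in canonical order (singletons,
pairs, triples, all four). Outer folds leave out all visits of one patient.
Per fold: features are z-scored on the training rows only (zero-variance
columns dropped for that fold and recorded as zero coefficients); the λ
path is 50 log-spaced values in [10⁻⁴·λ_max, λ_max] with
λ_max = max_j |x_jᵀ(y − ȳ)|/n (the smallest penalty zeroing all
coefficients); an inner stratified patient-level 3-fold CV picks the λ
maximizing mean inner AUC, exact ties resolved to the larger (sparser) λ.
The inner path is solved by a batched FISTA proximal-gradient sweep over
the whole grid (intercept unpenalized) — it only *ranks* penalties; the
final per-fold model is refit with liblinear (pinned random state). Five
repetitions differ only in the inner splits; each visit's pooled
probability is the median of its five held-out probabilities, and the
pooled AUC is the rank-based (ties half credit) AUC over all visits,
cross-checked in tests against brute-force pair counting. Popularity is
the fraction of all reps × patients models with |coefficient| > 10⁻¹⁰,
reported on the exact 1/#models grid.

## Synthetic cohorts

The generator produces what the analysis assumes, not a physiological
simulation. Per 48-h visit on a 30-s latent grid: activity counts with a
24-h cosinor profile (default amplitude 40 counts, acrophase 15 h) plus
folded-normal noise; latent HR = 80 bpm + AR(1) (a = 0.9, σ = 2 bpm)
+ 6 bpm circadian + γ·(lagged normalized activity), with γ ≈ 0.15 so
activity drives HR one step ahead and never the reverse. Beat times come
from integrating the instantaneous rate and adding 3% multiplicative
jitter; deceleration episodes — 11-beat zero-mean ramps whose consecutive-
beat increment equals the visit's `dc_mean` (ms) — are injected at 200/h,
so measured PRSA-DC responds linearly to the handle while total recording
time is preserved (each deceleration is followed by a compensatory
acceleration, as in baroreflex recovery). SQI traces are Beta-distributed
per 60-s window per channel with mean degrading during high-activity
epochs. Missingness: one uniformly placed charging gap per 24 h (default
2 h) plus Poisson dropouts (0.5/h, exponential mean 5 min).

Cohorts default to 20 patients, 1–3 visits each (≈ 32 visits), an even
severity split, and a deceleration-amplitude group gap expressed in
between-visit SDs (`dc_effect`; default 2, the calibration experiments use
3); high-severity visits also get a wider coupling spread. All outputs are
pure functions of the master seed via spawned seed sequences.

What passing tests show — and what they do not. The generator reproduces
the *statistical structure* the method exploits (directional coupling,
circadian rhythm, severity-linked DC, realistic gaps); it does not emulate
ECG morphology, breathing, movement artifacts correlated with arrhythmia,
or the label noise of clinician ratings, so recovery results bound what
the pipeline can do under its own assumptions, not clinical performance.

## Problem sizes in the shipped experiments

The cohort-level calibration and null experiments run on a compact
per-visit summary table (nocturnal DC mean/variance, HR level and spread,
RMSSD, PNN50, IS, IV, cosinor amplitude, the two scale-1 activity↔HR
transfer entropies, and two scale-5 network metrics — 13 columns) rather
than the full 396-feature pipeline: a single full-fidelity visit costs
minutes, and the calibration questions (is a configured DC gap recovered
as high pooled AUC with DC on top of the popularity ranking? do null
cohorts sit at chance?) do not require the complete block. The full
396-column pipeline is exercised end-to-end on miniature cohorts
(4 patients, 2 surrogate members, 300-s window shift) in the test suite;
its defaults (100 members, 30-s shift) are the full-fidelity settings.

A null 20-patient cohort's pooled AUC has an SD of ≈ 0.14 from
patient-level clustering alone (≈ 30 visits in 20 patients), so
chance-level behavior is asserted about the centre of the null
distribution (95% confidence band of the mean over 20 cohort seeds inside
[0.35, 0.65]), not about each individual seed; per-seed in-band counts are
reported alongside.

## Known limitations

- `simple_bsqi` is a stand-in quality index, not a validated bSQI; it is
  monotone in noise and separates clean from noisy windows, nothing more.
- The TE estimator's projected-marginal construction trades a small bias
  (and occasional small negatives) for speed and simplicity; k-NN
  estimators would be more accurate at small n.
- Surrogate imputation assumes local stationarity; donors spanning regime
  changes (e.g. sleep onset) import the neighbouring regime's dynamics.
- The noise term's 0.05·μ_S mean shift (see above) follows the pinned
  definition; centring the noise would be a one-line change.
- DFA α2 needs ≥ 64-beat boxes and degrades on short windows; it is
  reported as 0 when undefined rather than dropping the window.
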