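# Methods

This note documents the models, conventions and numerical choices behind
each stage of the pipeline, what the synthetic generator does and does
not emulate, and the known limitations.

## Synthetic RR cohorts

The generator produces one beat sequence per subject under a simplified
additive model: the instantaneous RR value at time *t* is

    RR(t) = mean_rr + Σ_band A_band · sin(2π f_band t + φ_band) + ε(t),

where the three sinusoids sit at configurable center frequencies inside
the canonical VLF/LF/HF bands (defaults 0.01, 0.10, 0.25 Hz), the phases
are drawn uniformly per subject, and ε is fractional Gaussian noise (fGn)
with a per-class target Hurst exponent, scaled to `noise_sd_ms`. Beats
are laid down sequentially: each beat time advances by the RR value
evaluated at the current time, and generation stops once the cumulative
span reaches the requested duration (default 300 s; the final beat may
overshoot and is kept). A floor of max(0.1·mean_rr, 100 ms) guards
positivity.

fGn is generated by circulant embedding (Davies–Harte): the fGn
autocovariance is embedded in a nonnegative circulant whose FFT
eigenvalues weight complex Gaussian draws, giving samples with the exact
target covariance for any H in (0, 1). This makes Hurst-recovery tests
real parameter-recovery tests rather than self-consistency checks.

Class defaults emulate the contrast a hypertension study expects:
controls at mean RR 850 ms with a strong respiratory (HF, 35 ms)
component and Hurst 0.7; patients at 700 ms (elevated heart rate) with
blunted HF (12 ms), raised VLF (35 ms) — hence higher LF/HF and VLF
share — and Hurst 0.85 (reduced complexity). Cohort sizes default to
30 + 40 so a stratified 5-fold split yields exactly 6 + 8 subjects per
fold. Where the study design fixes no value, these are one-time choices
of plausible short-term-HRV magnitudes and are not tuned.

Artifact injection replaces ⌊fraction·N⌋ random beats with mean ±
scale·SD outliers (scale > 3 so the downstream rejection rule can see
them) and records the positions for test oracles.

The generator deliberately omits: respiratory sinus-arrhythmia coupling,
an integral-pulse (IPFM) cardiac mechanism, nonstationary orthostatic
transitions, and ectopic-beat morphology. Passing tests therefore show
that the *feature machinery* recovers planted band structure, scaling
and class contrast — not that any classifier result transfers to
clinical recordings.

## Preprocessing

Artifacts are beats with |x − mean| > 3·SD, with mean and SD computed
once over the raw series (single pass; an iterated rule would depend on
removal order — the convention is stamped into the NN metadata). A
constant series (SD = 0) keeps all beats. Beat times of the cleaned
series are cumulative sums of the *kept* intervals: removed durations
are excised, not bridged. The tachogram is a natural cubic spline of NN
value against beat time, evaluated on a 10 Hz grid anchored at the first
beat time, never extrapolating beyond the last knot.

## Time-domain features

RMSSD divides the sum of the N−1 squared successive differences by N —
this matches the source formulation of the feature bank rather than the
more common N−1 divisor; the difference is a factor √(N/(N−1)) and is
irrelevant to any monotone classifier. HR is reported in beats/min
(60000/M). The NN histogram uses 50 ms bins anchored at the series
minimum; the mode M0 is the tallest bin's center (first bin on ties)
converted to seconds, and AM0 is the tallest bin's share of beats in
percent — percent rather than a raw count so the Baevsky indices do not
scale with recording length. A constant series is degenerate: M0 is the
value itself, AM0 = 100%, VR = 0, and the three VR-dividing indices (SI,
IAB, ARI) are reported missing.

## Fourier spectral features

The estimator is an averaged modified periodogram (Welch): Hann window,
50% overlap, linear detrend per segment, segment length
min(record, 150 s). On a 300 s record the 1/150 Hz resolution resolves
the VLF band only coarsely near its 0.003 Hz edge; the segment length is
config-exposed and stamped into the spectrum metadata so results are
auditable. Band powers integrate the PSD (trapezoid) over half-open
bands [low, high) to avoid double counting at 0.04 and 0.15 Hz. Total
power is defined as VLF+LF+HF — ULF is not analyzed on short records —
which makes the normalized shares sum to one exactly. HFmax is the PSD
maximum inside the HF band and RF its frequency, so RF ∈ [0.15, 0.4) by
construction.

## Wavelet features

The continuous wavelet transform uses the Coiflet-5 basis through the
integrated-wavelet algorithm (convolution with the rescaled integral of
ψ followed by differentiation), with scales mapped to frequency by
a = f_c·f_s/f and each band tiled log-uniformly with ≥ 8 voices per
octave. Because a real-valued wavelet's squared coefficient oscillates
through zero at twice the analyzed frequency, instantaneous band power
is computed from the analytic pair — ½(W[x]² + W[H x]²) with H the
Hilbert transform — which yields a smooth envelope; band features are
time-integrals of these series, and normalized shares and ratios are
unaffected by the common scaling. Cone-of-influence samples at the
record edges are retained (edge effects are visible in the first/last
few wavelet periods of the largest VLF scales on a 300 s record).

The LF/HF ratio series is floored (samples with HF power below 10⁻⁶ of
its mean are excluded) and smoothed with a 1 s moving average before
thresholding (window config-exposed; 0 disables). A dysfunction is a
maximal contiguous run of finite samples with ratio > Δ (default 10).
Its *intensity* is the area above the threshold, Σ(ratio − Δ)·dt — an
excursion integral chosen as the standard measure of supra-threshold
load; the mean supra-threshold value is available via configuration. In
the cohort feature table (LF/HF)max is encoded as 0 when no dysfunction
occurs (the run-level summary reports it as missing), keeping the table
free of structural missing values.

## Fractal features

The Hurst exponent is the least-squares slope of log σ_rms(ΔX) against
log s, where X is the cumulative sum of the mean-removed NN series and
σ_rms(ΔX) the standard deviation of increments over span s, on 8
log-spaced spans between 10 samples and n/10. The estimate is computed
in the beat domain (no interpolation), carries the fit's r², and is
mildly biased downward for strongly persistent series because mean
removal constrains the profile; the bias stays within the ±0.12
recovery band asserted by the tests.

MFDFA follows the standard scheme: profile = cumulative sum of the
mean-removed 10 Hz tachogram; nonoverlapping segments of length s taken
from both ends of the record; second-degree polynomial detrending per
segment; fluctuation function F(q, s) = (mean F²(v,s)^{q/2})^{1/q} with
the q = 0 case via exp(½·mean ln F²); H_x(q) by least squares in log-log;
τ(q) = q·H_x(q) − 1 (so τ(0) = −1 identically); α = dτ/dq by central
differences (one-sided at the grid ends); D(α) = q·α − τ. The q grid is
21 points, step 0.5, in [−5, 5]. Scale bands follow the LF (6–25 s) and
VLF (25–300 s) oscillation periods; the HF band is excluded as too noisy
to be informative. The VLF band's nominal upper scale equals the record
length, so scales are capped to n/4 samples (≈75 s on a 300 s record) to
guarantee at least 4 segments; the cap is recorded in the spectrum
metadata. Zero-variance segments are floored at the smallest positive
float, and an all-zero record is an error.

## Combination search

Pearson correlation (Spearman selectable) is computed once on the full
cohort, pairwise-complete over missing values; zero-variance columns get
missing correlations and can never enter a combination. The screen keeps
subsets whose every pair satisfies |r| < 0.25 — the absolute value, since
a strong negative correlation is as redundant as a positive one — with
strict inequality at the boundary. Enumeration is depth-first and
incremental: a partial subset is extended only by columns compatible
with all current members, so runtime scales with the accepted set, not
with C(n_features, n). Equivalence with the brute-force filter is tested
exhaustively up to 20 features.

## Cross-validated evaluation

Folds are stratified random partitions (each class split as evenly as
possible across the 5 folds), drawn fresh per repetition from seeds
derived from the master seed. A repetition's score is the mean of its 5
fold accuracies; the reported value is mean ± SD over the 100 repetition
scores, in percent (the SD over all 500 fold scores is selectable; with
a single repetition the SD is over its fold scores). Accuracy is the
overall fraction correct. Features enter the classifiers unscaled by
default — scaling is a config switch stamped into result metadata —
because the benchmark's discriminants and trees are scale-equivariant
and the kNN/SVM configurations are defined on the raw feature scale.

Classifier configurations are fixed, not tuned: LDA; QDA (ridge 10⁻⁶);
kNN with k = 3, 4, 5 (Euclidean, majority vote; sklearn breaks even-k
ties by neighbor order); SVC with RBF kernel, γ = 2, C = 1; decision
trees (Gini) with depth cap 5 and uncapped; Gaussian naive Bayes. When a
training fold leaves a class covariance rank-deficient, the discriminant
families fall back to regularized fits (LDA: least-squares solver with
automatic shrinkage; QDA: class-conditional Gaussians with ridge
λ = 10⁻⁶·trace/d, escalated tenfold until the covariance factorizes).

The PCA arm z-scores every non-degenerate column, takes principal
components of the standardized matrix, reports explained and cumulative
variance per component, and pushes combinations (sizes 2–5) of the first
10 component scores through the identical repeated-CV machinery. Sizes
2–5 mirror the main search; evaluating all 2¹⁰ subsets would change the
comparison's footing without changing its conclusion.

## Determinism and problem sizes

Every stochastic step (generation, artifact placement, fold draws,
repetition seeds) derives from explicit integer seeds via spawned
`numpy` SeedSequences, and identical configuration + seed reproduces
output files byte for byte. The test-suite and acceptance-script runs
use desk-scale problem sizes — 70-subject cohorts, 300 s records,
pair-sized combination sweeps, 5–20 CV repetitions — chosen so the full
pipeline re-runs in minutes on one CPU; all thresholds asserted by the
tests (band-share > 0.9, Hurst ±0.12, monofractal width < 0.35,
blob accuracy ≥ 99%, shuffle ≈ 50%) are stated at these sizes.

## Known limitations

- The synthetic cohort is far easier to classify than clinical data
  (the classes differ by construction); accuracy values on it
  characterize the machinery, not the clinical problem.
- The Welch estimator under-resolves the lowest VLF octave on 300 s
  records; VLF(Fr) is best read as a band aggregate, not a line power.
- CWT edge effects inflate VLF(wt) variance within roughly one largest
  scale of the record ends.
- The aggregated-variance Hurst estimator's small negative bias for
  H ≳ 0.8 is documented above and bounded by the test band.
- kNN with even k inherits sklearn's neighbor-order tie-breaking, which
  is deterministic but arbitrary.
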