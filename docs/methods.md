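# Methods

`memdecode` implements a time-resolved multivariate decoding and
representational-similarity analysis (RSA) for epoched multichannel
recordings, of the kind used to study stimulus memorability with MEG, and a
synthetic-data generator that reproduces the statistical structure the
analysis assumes.  This note documents the models, the numerical choices,
and what the synthetic benchmarks do and do not establish.

## Analysis pipeline

### Preprocessing (epoch domain)

Per subject and trial: per-channel baseline-mean removal (default window
−100..0 ms), zero-phase low-pass filtering (4th-order Butterworth applied
forward–backward, default cutoff 20 Hz), rejection of trials whose maximum
absolute amplitude exceeds a threshold (default 6000, in the data's units;
per-channel-group thresholds are supported for mixed sensor types), and
blink-artifact removal: blink events are detected as peaks of the
frontal-channel RMS z-score (default z > 4), peri-event segments (±200 ms)
are pooled across trials, and the leading spatial principal components of
the pooled segments (up to 90% of pooled variance, capped at 2 components)
are removed from all data by orthogonal projection.  The filter has no named
design requirement beyond its passband/stopband contract (≤5% passband
loss below half the cutoff, ≥20 dB attenuation above three times the
cutoff), which the tests verify with sinusoid-fit oracles.  Blink removal
operates on epoched data; the cap of two removed components guards against
degenerate PCA on small inputs.

### Pairwise decoding and RDMs

Trials of each image are sub-averaged in randomly assigned groups of
*g* = 5 into pseudo-trials (remainder trials are discarded at random;
repeating the procedure R times marginalises the loss).  For each image
pair and time point, a linear support-vector machine (libsvm backend,
C = 1, no scaling — feature vectors are the raw channel values at one time
point) is evaluated with a *paired* leave-one-out schedule: fold *k* holds
out pseudo-trial *k* of each image and trains on the remaining 2(N−1)
vectors, keeping every training set balanced.  Accuracy is the percentage
of correct held-out classifications over all 2N tests.  Decision values of
exactly zero classify as the first image (a deterministic tie-break that
matters only on degenerate inputs).  Accuracies averaged over the R
sub-averaging repetitions populate a symmetric, zero-diagonal K×K
dissimilarity matrix per time point (the RDM series).

Temporal generalization reuses the classifiers trained on the diagonal
fold schedule and tests the same held-out pseudo-trials at every other
time point, so the matrix diagonal is bit-identical to the 1-D time course
under the same seed.  (Retraining per train/test pair would be an
alternative; the reuse choice is recorded in output metadata.)
Region-of-interest decoding is the same code path with a channel-group
selector.

### RSA

Two hypothesis RDMs over the same images: *categorical* (between-condition
pairs 1, within-condition 0 — two linearly separable clusters) and
*dispersion* (within-high 1, between 0.5, within-low 0 — high-memorability
exemplars spread around the same centroid the low-memorability exemplars
cluster tightly about).  The between-condition value 0.5 reflects that,
with a shared centroid, expected between distances lie between the two
within-condition distances; because the comparison is Spearman rank
correlation (average ranks for ties), any coding preserving this ordering
gives identical results, and an option to mask between pairs out entirely
is provided.  Correlations are computed per subject per time point over
the masked lower triangle; time points with zero variance in the measured
entries yield rho = 0 and are counted in the result's metadata.
Group-level inference treats the per-subject rho curves exactly like
accuracy curves (no Fisher transform; the group test is nonparametric).
Classical (Torgerson) multidimensional scaling — double-centred squared
dissimilarities, top-2 spectral coordinates — is provided for
visualization only.

### Statistical inference

Cluster-size permutation tests: pointwise one-sample t statistics against
chance (50% for accuracies, 0 for differences and correlations) are
thresholded at the cluster-defining p (default 0.05, one-sided for
directional hypotheses); contiguous supra-threshold runs (1-D) or
4-connected components (2-D) form clusters whose *sizes* are compared with
the null distribution of the maximum cluster size over whole-series
sign-flips of the subject deviations (default 1000 flips; the exhaustive
set is used, with a warning, when 2^n_subjects is smaller).  Cluster
p-values use the (1 + exceedances)/(n_perm + 1) correction.  Two design
notes:

- The t-based cluster statistic is scale-invariant, so a uniform effect
  spanning the whole tested axis cannot reach the minimal p-value
  1/(n_perm+1): permutations flipping only a few subjects still exceed the
  threshold everywhere, giving an irreducible p floor of roughly
  P(Binom(n, ½) ≤ k*) for the k* at which the flipped t drops below
  threshold.  This is a property of all scale-invariant cluster statistics,
  not an implementation artifact.
- Thresholding uses parametric t quantiles; the permutation null makes the
  cluster-level inference nonparametric regardless of that choice.

Peak latencies carry bootstrap confidence intervals: subjects are resampled
with replacement (default 1000 draws), each resample's mean curve
contributes its argmax, and the CI is the percentile interval of that
distribution.  Wilcoxon signed-rank p-values are exact for n ≤ 25 via a
dynamic-programming convolution over doubled average ranks (handles ties,
drops zeros), with a tie-corrected normal approximation beyond.
Signal-detection d′ = z(hit rate) − z(false-alarm rate) with rates clipped
to [1/(2n), 1−1/(2n)] per response class, so perfect rates stay finite and
negative sensitivities remain representable.

## Synthetic cohorts

Each image *i* has two prototype patterns over channels: an early identity
pattern u_i (spherical normal, per-channel scale σ_id = 0.6, independent of
condition) switched on at t_early = 70 ms and sustained, and an
effect-window pattern v_i = c + r_i active only within [t_on, t_off] =
[149, 228] ms.  The dispersion residuals r_i lie on a sphere of radius
σ_cond·√S (uniform random direction; S = channel count), with
σ_high = 1.0 and σ_low = 0.3, around a centroid c shared by both
conditions.  Trials are
gain · (g_early(t)·u_i + g_window(t)·v_i) + ε(t), with raised-cosine
envelope ramps (5 ms; boxcar optional), per-subject gain jitter
(SD 0.1) so subjects are exchangeable but not identical, and temporally
smooth AR(1) Gaussian noise (coefficient 0.9 at 1 kHz, rescaled as
0.9^(1000/fs) at other rates; white noise would make decoding
unrealistically easy).

Two generator design choices deserve explanation:

- **Fixed-radius dispersion residuals.**  With Gaussian residuals the
  within-high pair-distance distribution is broad and overlaps the
  between-condition distribution asymmetrically, which makes the
  categorical hypothesis RDM *systematically* positively rank-correlated
  with the true geometry (Monte-Carlo: mean Spearman ≈ +0.05, independent
  of the image count) — the opposite of the geometry the generator is
  meant to embody.  Fixed-radius residuals preserve the second moment
  (E‖r_i − r_j‖² = 2Sσ² exactly, which the tests verify against the
  closed form) and the dispersion ordering, while concentrating between
  distances strictly between the within-condition distributions; the
  residual categorical correlation drops to ≈ +0.01, below any realistic
  detection threshold.
- **Noise calibration.**  The noise SD default is 12.0 per channel at a
  64-channel reference, rescaled by √(S/64) so the pattern-level
  signal-to-noise ratio — which grows as √S for fixed per-channel scales —
  is invariant to channel-count reductions.  The value was calibrated once
  so that pairwise decoding sits in the realistic mid-range (identity
  epoch ≈ 55%, within-high window ≈ 70%).  At appreciably lower noise,
  accuracies saturate near ceiling; the concave distance→accuracy mapping
  then compresses within-high against between-condition entries and
  re-introduces a spurious categorical correlation, besides erasing the
  high−low difference entirely.  SNR is therefore not a free dial: the
  calibrated regime is part of the study conditions the benchmarks assume.

The generator records the drawn prototypes as ground truth, supports a
pure-noise mode (all signal scales zero) for chance calibration and
false-positive studies, and can inject spatially fixed blink-like
transients for preprocessing tests.  Cohort seeds are spawned
deterministically from a single seed (global → prototypes → subject), and
identical configurations reproduce byte-identical cohorts.

### What the synthetic benchmarks show — and what they do not

The default full-scale configuration is 15 subjects, 15 + 15 images,
30 trials per image; the benchmark suite runs a reduced desk scale
(10 subjects, 10 + 10 images, 20 trials per image, 24 channels, 100 Hz,
one sub-averaging repetition, 500 permutations) chosen so that the whole
suite completes in minutes while retaining the power the recovery checks
need.  On these cohorts the suite verifies: family-wise error control of
the cluster test on null cohorts; chance-level decoding (50%) on
signal-free epochs; recovery of the injected effect window by the
high−low difference cluster (onset within ±20 ms of t_on); and the
geometry contrast — a significant dispersion-model correlation cluster
overlapping the window with no significant categorical-model cluster.
These are checks of the *pipeline's* correctness and sensitivity under the
generator's assumptions (isotropic prototypes, spatially white AR(1)
noise, a single dispersion window).  They do not estimate the SNR,
latencies, or effect sizes of any real recording, and real data's spatial
noise correlations, inter-subject variability and overlapping processes
are outside what passing these tests demonstrates.

## Degenerate inputs and tie-breaks

Validation rejects empty trial sets, non-uniform time axes, images
appearing in both conditions, and non-finite data, naming the violated
invariant.  Zero-variance time points in RSA give rho = 0 (flagged);
flat time courses take the earliest maximum as peak; all-zero signed-rank
differences give p = 1 with a warning; SVM decision ties break toward the
first class.  Sub-averaging requires at least one full group per image and
truncates all images to a common pseudo-trial count within a repetition.

## Reproducibility

Every stage consumes an explicit seed; hierarchical `SeedSequence`
spawning (global → subject → repetition) lets any stage re-run in
isolation.  Pipeline outputs (RDM tables, time courses, cluster JSONs)
carry JSON sidecars naming the parameters and seeds that produced them,
and two runs from the same configuration are byte-identical.
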