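# Methods

This note documents the models, conventions, and design choices behind
`sleepshift`, in the spirit of a statistical package's methods appendix.

## Problem setting

A *sleep session* is one participant's night: raw wearable signals (heart
rate, inter-beat intervals, skin temperature, triaxial acceleration,
blood-volume pulse) plus a morning self-report with a Likert sleep-quality
score. Sessions are reduced to fixed-dimension feature vectors and the task
is binary classification of perceived sleep quality. Two cohorts collected
with similar devices and protocols still differ in their feature marginals
(*covariate shift*): a model trained on one cohort meets a different
`P(X)` at deployment while `P(Y|X)` is assumed unchanged.

## Feature extraction

**Descriptive signal features (HR, ST, ACC, RP; 12 each).** Eight
time-domain statistics — mean, sample SD (ddof = 1), min, max, median,
skewness, excess kurtosis, IQR (linear-interpolation percentiles) — and four
FFT features computed on the mean-removed, Hann-windowed signal: total
spectral power, dominant frequency, spectral entropy normalized by
`log(#bins)`, and the fraction of power below half the Nyquist frequency.
Conventions for degenerate input: zero-variance signals have skewness and
kurtosis 0 and all four spectral features 0. The exact 12-feature list is a
convention of this package (the literature varies); dimensions match the
canonical 67/71 concatenations.

**HRV (19).** The IBI series is cleaned in two steps: intervals outside
300–2000 ms are dropped, then Malik's rule removes any interval differing by
more than 20 % from the last *accepted* interval (the first in-range
interval seeds the comparison; cleaning is idempotent). Twelve time-domain
statistics (meanNN, medianNN, SDNN, RMSSD, SDSD, NN50, pNN50, NN20, pNN20,
rangeNN, CVNN, CVSD) and seven frequency-domain ones (VLF 0.0033–0.04 Hz,
LF 0.04–0.15 Hz, HF 0.15–0.4 Hz band powers via Welch on the NN series
linearly interpolated to 4 Hz; their sum; LF/HF; LF and HF as % of LF+HF).
Ratios are defined as 0 when their denominator vanishes. At least 10 cleaned
intervals are required.

**Respiration pattern (RP).** The respiratory waveform is extracted from
the PPG by a zero-phase order-3 Butterworth band-pass over 0.1–0.5 Hz,
resampled to 4 Hz. Zero-phase filtering doubles the effective attenuation
(≥ 20 dB one octave below the band edge), so slow drift does not leak into
the respiratory band.

**Contextual (4).** Time in bed (wake − bed modulo 24 h), latency,
awakenings, bedtime in minutes since midnight. Which four self-report
fields to use is a declared convention of this package.

**Labels.** High sleep quality iff score ≥ 4 on a 5-point scale or ≥ 7 on a
10-point scale; other scales are rejected rather than silently generalized.

## Shift diagnostics

Per-feature two-sided two-sample KS tests (asymptotic p-values) are flagged
at `α` and at the Bonferroni level `α_n = α/n`; `n` defaults to the feature
count but is exposed as a parameter. The name-the-dataset probe fits a
linear-kernel SVM (C = 1, features standardized by training statistics) to
predict dataset identity on user-disjoint splits, scored by balanced
accuracy against a uniform random-guess baseline, with a two-sided paired
Wilcoxon comparison across rounds. Cliff's δ is computed exactly by a
rank-based formula (midranks handle ties) and labelled by the
Vargha–Delaney thresholds 0.147 / 0.33 / 0.474.

## Models and evaluation

**Classifier families.** The online max-margin linear family is PA-I,
implemented as `SGDClassifier(loss="hinge", penalty=None,
learning_rate="pa1", eta0=1.0)`; the network family is an MLP with one
hidden layer of 100 units, max 500 epochs, no early stopping. Inputs are
standardized with statistics frozen at pretraining; hyperparameters are
library defaults declared in `ClassifierSpec` so they are auditable.

**Prequential personalization.** The personalized model starts from the
population fit and, for each element of the target user's chronologically
ordered stream, predicts *first* and only then takes a single-example
update (no replay buffer). Prequential accuracy over the whole stream is
identically the plain accuracy of the recorded predictions. An unsorted
stream raises — the temporal-leakage guard.

**Scenarios.** `single` = leave-one-participant-out within a dataset;
`mixed` = the pooled-cohort variant; `multiple` = leave-one-dataset-out
composed with per-user evaluation (the covariate-shift stress test). The
test user's data never enters training (asserted structurally). Experiments
repeat over model seeds; the reported standard error is the SD of per-seed
user-means over √(#seeds) — the replication unit the literature leaves
ambiguous, declared here. Model comparisons use Cliff's δ on per-(user,
seed) accuracies and a paired Wilcoxon on user-level means. Degenerate
splits (single-class training sets) are skipped and recorded, never
silently dropped. Plain accuracy is the metric for the sleep task; balanced
accuracy is reserved for the NED probe.

**Baselines.** RG draws uniformly; BRG draws from the frozen training label
distribution; PBRG folds each observed stream label into that distribution
before the next draw.

## CBPM

Hyperparameter ablation evaluates every pair on the default grids
`min_cluster_size ∈ {5, 10, 15, 20, 25}` × `min_samples ∈ {1, 5, 10, 15}`
(the grids are configuration, not dogma), scoring each by the silhouette of
the non-noise points in z-scored feature space; fewer than two clusters
scores −1; ties break toward larger `min_cluster_size`. Training drops
noise points and fits one classifier per cluster; a single-class cluster
borrows opposite-class vectors from the other clusters (uniform, seeded,
without replacement, up to the majority count). Centroids use only original
members. At inference a vector inherits the cluster of its nearest training
point; if that neighbour is a noise point, it falls to the nearest centroid
(Euclidean, standardized space, ties toward the lower cluster id) — so
every vector gets exactly one prediction. Training rows are canonically
ordered before fitting, making the fit invariant to input permutation.
CBPM is evaluated in the multiple-dataset scenario, its intended regime.
HDBSCAN comes from scikit-learn, which offers no approximate-predict for
unseen points; the nearest-training-point membership step stands in for it
ahead of the centroid fallback.

## Synthetic data

The feature-level generator draws, per session, an archetype `k ∈ {1..K}`
uniformly; features are `N(μ_k + u, I)` with a per-user offset
`u ~ N(0, σ_user² I)`. Archetype means sit on mutually orthonormal
directions scaled so the pairwise distance between means equals
`archetype_separation` (in noise-SD units). Labels are
`Bernoulli(σ(w_k·(x − μ_k)))` with per-archetype weight vectors (orthonormal
by default, scaled by `label_sharpness = 4`), flipped with probability
`label_noise`; they are computed on the *unshifted* features, so adding
`shift_delta` to a `shift_fraction` of dataset B's features is pure
covariate shift. Defaults mirror the targeted study conditions: cohorts of
16 and 10 users, 30 nights each, 12 features, K = 3, separation 5,
`σ_user = 0.3`, 10 % label noise, shift off. The raw-signal generator
synthesizes a cardiac sinusoid with respiratory amplitude modulation *and*
respiratory baseline wander (the component band-pass respiration extraction
recovers), an IBI series with mean `60000/HR` ms, slow temperature drift,
and gravity-plus-bursts acceleration; it exists to exercise the extractors
and is not statistically coupled to the feature-level generator.

What the generator does not emulate: circadian structure, realistic PPG
morphology, label/concept shift, missing data, or feedback sparsity.
Passing tests therefore demonstrate correctness of the machinery and the
qualitative shift phenomenology, not performance on real cohorts.

## Experiment sizing and numerical choices

The bundled studies (`sleepshift.experiments`) run cohorts of 8 users per
dataset with 30-night streams, 12 (or 8) features, and the linear PA
classifier, averaging over independent data replicates; one replicate's
cross-scenario effect size depends on the random alignment between the
shift direction and the label rule, so Cliff's δ is pooled over 12
replicates (10 for the CBPM comparison). These sizes resolve the planted
effects clearly while each study completes in seconds. The archetype
recovery study uses 8 features and `σ_user = 0.2`, chosen so that the
between-archetype distance exceeds typical within-archetype pair distances
after z-scoring — density clustering cannot recover structure that
standardization has erased.

Known limitations: the descriptive-feature lists, the contextual-feature
choice, Malik's-rule comparison policy, and the HRV bands are documented
conventions where the field admits variants; the CBPM augmentation size
(balance-to-majority) is one reasonable reading of "borrow opposite-class
vectors"; and HDBSCAN on very small min-cluster sizes will carve spurious
micro-clusters out of unstructured noise, so grids should scale with the
training-set size.
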