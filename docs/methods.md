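# Methods

This note documents the models, estimators, parameter choices and known
limitations of the `affecteeg` pipeline.

## The analysis problem

A subject watches a sequence of movie clips while 8-channel
frontal/central EEG (F3, F4, Fz, F7, F8, C3, C4, Cz) is recorded; after
each clip they rate their affect on the 10-item short PANAS (five
positive-affect items: alert, inspired, determined, attentive, active;
five negative-affect: upset, hostile, nervous, ashamed, afraid; each
1–5). The task is to classify, per 8-s EEG epoch, binary valence and
arousal derived from those ratings, and to quantify what three feature
families — single-channel spectral/temporal, left–right asymmetry, and
multiscale entropy — contribute individually and combined.

## Synthetic sessions

No recording is publicly available, so the `synthgen` module generates
sessions carrying exactly the statistical structure the downstream
analysis assumes, making every stage testable end to end.

Signal model, per channel and segment: pink noise (power ∝ 1/f above a
1 Hz cut-off) plus five oscillators at the band centres (δ 3 Hz, θ 6,
α 10, β 20, γ 35 Hz) with AR(1)-smoothed frequency jitter, mixed as

    x = 10 · ( √(1−ν)·osc/‖osc‖ + √ν·pink ),

where ν is the broadband-noise ("irregularity") fraction. Affect enters
as:

* **valence** → frontal alpha asymmetry: the F4/F3 alpha amplitudes are
  scaled by exp(±asym_effect/4) so the ln-alpha-power difference
  ln Pα(F4) − ln Pα(F3) shifts by +asym_effect for positive and
  −asym_effect for negative clips (greater relative right-frontal
  activity, i.e. lower right alpha, for negative valence, per the
  approach/withdrawal model); F8/F7 get half the effect;
* **arousal** → alpha divided and beta multiplied by
  (1 + arousal_effect) on all channels, and ν shifted by
  ±0.5·complexity_effect (clipped to [0.05, 0.95]) so complexity
  features carry arousal information.

`expected_band_power` states the model's own band powers analytically
(oscillator share + logarithmic pink-noise share); a Welch estimate on
generated epochs agrees within ~10 %, which the tests assert.

Artifacts: blinks are 0.4-s Gaussian bumps of ~300 units with spatial
weights F7/F8 (1.0) > F3/F4/Fz (~0.5) > central (0.2); motion events
are 1–3-s smooth drifts of ~400 units on all channels; flatlines zero
one channel's variance for a whole epoch. Counts follow Poisson laws at
the configured per-minute rates. Defaults — 8 blinks/min, 0.5 motion
events/min, flatline probability 0.005 per channel-epoch — emulate a
naturalistic dry-electrode session with substantial frontal ocular
contamination. Every event is logged in the ground truth, which the
quality tests use to measure detection recall.

Ratings: each s-PANAS item is a linear base map of the true classes
(positive valence: positive items +1, negative items −1, and vice
versa; high/low arousal: all items ±0.5; midpoint 3) plus Gaussian
noise of sd `panas_noise_sd`, rounded half-up and clipped to 1..5. With
zero noise the published scoring rules recover the true classes
exactly, making label recovery a well-posed parameter-recovery
experiment.

What the generator does **not** emulate: volume conduction and
realistic cross-channel covariance, non-stationarity within a clip,
inter-subject anatomical variability, or genuine emotional dynamics.
Passing tests therefore demonstrate correctness of the pipeline and
recoverability of encoded effects — not field performance on real EEG.

The sampling rate is configurable (default 256 Hz; it must exceed
90 Hz so the gamma band up to 45 Hz exists, and 102 Hz for the notch
filter). The bundled study configurations use 128 Hz, which resolves
every band of interest at a quarter of the computational cost.

## Preprocessing

5th-order Butterworth band-pass (2–45 Hz) and band-stop (49–51 Hz),
designed as second-order sections (direct forms of order-10 band-pass
prototypes are numerically fragile at low normalized edges) and applied
forward–backward. Zero-phase filtering keeps epoch boundaries
phase-aligned at the cost of doubling the effective attenuation — both
properties are asserted by frequency-response tests. Movie segments
follow the timeline markers exactly (neutral lead-ins are excluded);
each segment is cut into ⌊duration/8 s⌋ non-overlapping epochs and the
trailing remainder is discarded, so all features see equal-length
windows. Note the band-pass lower edge (2 Hz) truncates the nominal
delta band (1–4 Hz); effective delta content is 2–4 Hz.

## Quality gating

Each channel-epoch gets score = (tripped flags)/(flags) ∈ [0, 1] with
four flags: amplitude (|x| > 150 units), flatline (variance < 1e−8),
high-frequency noise (>30 % of spectral power above 40 Hz), clipping
(≥20 consecutive identical samples at ≥95 % of the amplitude bound). A
contact-impedance flag joins when an impedance trace is provided.
Thresholds are config-exposed. Only score = 1 (every flag tripped —
certain-bad) masks a channel-epoch; partially flagged data flows on to
the imputation rules. Scoring runs on the *unfiltered* epochs: zero-
phase filtering removes the DC pedestal of saturated spans and smears
flat spans with ringing, hiding exactly the artifacts the detector
looks for.

## Feature families

* **Band power**: Welch PSD (2-s Hann windows, 50 % overlap), integrated
  over δ 1–4, θ 4–8, α 8–13, β 13–30, γ 30–45 Hz.
* **Differential entropy**: Gaussian closed form ½ln(2πe·σ²) on the
  variance of the band-filtered epoch — the dominant convention for EEG
  affect features; zero variance maps to a missing value.
* **SampEn / ApEn**: template statistics with m = 2,
  r = 0.2·SD, Chebyshev distance. SampEn excludes self-matches and
  counts both lengths over the same N−m template positions; ApEn
  includes self-matches (always defined). Both equal an independent
  double-loop implementation exactly, which the suite asserts on random
  fixtures.
* **Higuchi fractal dimension**: curve-length slope over k = 1..8
  (kmax config-exposed); ramp → 1, white noise → ≈2.
* **Asymmetry**: DASM = ln P_right − ln P_left and, literally,
  RASM = ln P_right / ln P_left per band and homologous pair. The
  alternative reading ln(P_r/P_l) coincides with DASM and is therefore
  not a separate feature.

## Multiscale entropy

Scales come from empirical mode decomposition, not coarse-graining: the
five frontal channels are decomposed jointly with multivariate EMD
(64 direction vectors from an unscrambled Halton sequence mapped to the
unit 4-sphere; cubic-spline envelopes with two mirrored boundary
extrema; Cauchy stopping SD < 0.2; extraction capped at ⌊log₂N⌋ IMFs).
Joint sifting aligns IMF indices to similar frequency bands across
channels and guarantees a common IMF count. Envelopes use a natural
cubic spline implemented as a banded tridiagonal solve — sifting builds
thousands of envelopes per epoch and this is the pipeline's hot path.

Per retained IMF and channel, quadratic Rényi entropy is estimated
nonparametrically from the data kernels (Gaussian kernel, Silverman
bandwidth):  H₂ = −ln((1/N²)Σᵢⱼ G(sᵢ−sⱼ; 2h²)), the information-
potential estimator (pairwise sums in float32, accumulated in float64).
Order α = 2 is chosen because it admits this closed-form estimator;
other orders use the KDE resubstitution estimator. The decomposition is
capped at n_scales + 1 = 7 IMFs and the last extracted one is treated
as the trend and excluded, leaving a fixed 6 scales × 5 channels = 30
features whose names align across epochs; epochs the decomposition
cannot reach that depth for yield missing values handled by the
imputation rules. Entropy is computed per 8-s epoch per channel, the
same aggregation window as every other family. A caution on the
estimator: under a variance constraint the maximizer of H₂ is not the
Gaussian (compact-support densities can exceed it), so the tests check
the ordering against *peakier* equal-variance densities
(Gaussian > Laplace > exponential) rather than a false maximality
claim.

## Labels, imputation, pooling

valence = Σ(positive items) − Σ(negative items) ∈ [−20, 20], positive
class iff > 0 (a score of exactly 0 is non-positive ⇒ negative);
arousal = Σ(all ten) ∈ [10, 50], low iff < 30 with the boundary 30
assigned to low. The two formulas satisfy valence + 2·Σnegative =
arousal identically, which is asserted as an invariant. An alternative
label source takes per-movie mean ratings of an independent panel,
scored and binarized identically (only labels change, never features).

Per movie: epochs with >50 % bad channels are dropped; columns with
≤20 % missing values are imputed with the within-movie observed mean
(which preserves the column mean exactly); rows carrying misses in
columns above 20 % are dropped — dropping rows rather than columns
keeps the feature space aligned across movies. For the multiscale
family a single masked frontal channel invalidates the joint
decomposition, so such epochs are entirely missing and removed. Cleaned
blocks are pooled over subjects per family and joined to the labels;
the manifest verifies raw = surviving + channel-rule-dropped +
imputation-dropped.

## Reduction and classification

Features are standardized, then PCA retains the leading components
reaching 95 % cumulative variance; features with |Pearson r| > 0.7 to
at least one retained component's score vector survive (a
loading-based reading is config-exposed). Standardization is necessary
because powers and entropies live on wildly different scales; a side
effect is that no column is "small" anymore, so discarding
low-variance columns must happen through the component-correlation
filter, not through raw variance. Correlation pruning then greedily
removes, from the worst pair at |r| ≥ 0.95, the member with the larger
mean absolute correlation to everything else (ties keep the earlier
column) until no pair reaches the cutoff.

Classification is a stratified 5-fold CV at the epoch level — subject-
dependent by design: epochs of one subject can appear on both sides of
a split. In each training fold, features are ranked by mutual
information with the binary target (equal-frequency 10-bin
discretization, so strictly monotone transforms don't change the
ranking; a k-NN estimator and raw-score MI are config alternatives) and
the top 10 feed a random forest (100 trees, unlimited depth, √p
features per split, fixed seed). The combined model takes the union of
the three families' in-fold top-10 lists (≤30 features). Selection
never sees the held-out fold; a dedicated test shows that full-dataset
selection on pure noise inflates F1 while the wired-in path stays at
chance. Performance is class-support-weighted F1; families are
compared with a one-sided rank-sum test on the per-fold F1 samples,
exact for combined n ≤ 10.

## Study configurations and problem sizes

The bundled label-recovery study uses 5 subjects × 16 movies × 60-s
clips at 128 Hz (560 raw epochs), asym_effect 2.0, complexity_effect
0.6, arousal_effect 1.0 and noise-free ratings — large encoded effects,
chosen so that recovery failure would indicate a pipeline defect rather
than statistical noise. The complementarity experiment uses per-seed
single-subject sessions (8 movies × 33 s) with valence encoded only in
band power/asymmetry and arousal only in irregularity, so no single
family carries both targets. Movie durations of 90–120 s and 64 clips
per session remain the generator defaults.

## Known limitations

* The quality detector is a pragmatic four-flag re-specification; the
  published 0–1 contract and the "remove only at exactly 1" rule are
  honored, but the original detector's feature set is proprietary to
  its reference and not reproduced.
* Requiring *all* flags to trip for removal means realistic single-mode
  artifacts (a blink, a lone flatline) are flagged but kept; data
  hygiene then rests on the imputation rules, mirroring the published
  contract rather than maximizing cleaning power.
* EMD has no uniqueness theory; a different envelope/stopping
  convention yields slightly different IMFs. All contracts asserted
  here (completeness, IMF-count bound, mode alignment, two-tone
  separation) are convention-independent.
* Subject-dependent CV overstates deployment performance by design;
  leave-subject-out evaluation is a config extension, not validated
  here.
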