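# Methods

This note documents the statistical models, the numerical choices, and the
scope of the synthetic data generator. Everything stated here is either a
definition or has been computed with this package; no empirical claims are
made beyond that.

## Time–frequency decomposition

Power at (channel, frequency *f*, center time *t*) is the squared magnitude
of the Hann-tapered discrete Fourier coefficient of the 500 ms data segment
centered on *t*:

    P(c, f, t) = | Σ_n w[n] x[n] e^{-i 2π f n / fs} |² / (Σ_n w[n] / 2)²

with a periodic Hann taper `w`, 50 ms hops and a 1 Hz frequency grid
(2–120 Hz computable; analyses use 2–60 Hz). The taper-energy
normalization makes a unit-amplitude sinusoid on the DFT grid yield power
exactly 1 regardless of window length (verified against a brute-force
oracle to 1e-8 relative tolerance). Window centers whose 500 ms segment
would overrun the epoch are **undefined (NaN)** — never zero-padded — and
all downstream stages treat them as missing.

Decibel baseline correction is `10·log10(P / P̄_base)` per observation,
channel and frequency, with `P̄_base` the mean power over window centers in
−1500…−500 ms. The correction is invariant under global amplitude scaling
and maps power ratios 1 and 10 to 0 and 10 dB exactly. Raw
(uncorrected) power feeds the decoders; dB maps feed the univariate
statistics.

### Temporal smearing

A 500 ms analysis window spreads any transient by ±250 ms around its
center. Two consequences are built into the package:

- **Strictly pre-stimulus features.** A time bin can only enter the
  decoding features if `center + window_length/2 ≤ 0`, i.e. its analysis
  window ends at or before face onset. For the default −1000…−200 ms
  feature window this keeps centers up to −250 ms. Perturbing all
  post-onset samples therefore changes no feature and no accuracy
  (asserted by test).
- **Edge dilution of realized contrasts.** When a band-limited effect
  occupies −500…0 ms, analysis windows centered near the effect edges
  overlap it only partially, so a band-power average over the whole effect
  window underestimates the injected contrast. The generator's realized
  dB contrast is therefore measured at centers whose analysis window lies
  fully inside the effect window (center −250 ms), where the nominal
  `effect_size_db = 3` is recovered within ±20% (measured ≈ 2.97 dB
  before re-referencing).

## Cluster-based permutation statistics

Per-point statistics over channel × frequency × time: paired *t* between
condition means across subjects, or Pearson *r* between per-subject
negative-minus-positive dB differences and the behavioral negativity bias.
Points are suprathreshold if they exceed the cluster-forming threshold,
either **parametric** (Student-*t* critical value at α per tail; for *r*
the *t* critical value mapped to the *r* scale with df = n − 2) or
**nonparametric-individual** (default): each point's own α and 1−α
quantiles of its permutation distribution.

Clusters are connected components of same-sign suprathreshold points,
where two points are neighbours if they share the (frequency, time) bin
and their channels are montage neighbours, or share the channel and are
adjacent in frequency or time. Channel neighbourhoods come from a
distance threshold over the 2-D projected sensor layout, auto-calibrated
to a median degree of ~6; isolated channels are attached to their nearest
neighbour. Cluster mass is the sum of member statistics; the null is the
Monte Carlo distribution of the **maximal** cluster mass per tail under
random within-subject condition swaps (sign flips of the differences) or
random covariate re-pairings (2000 randomizations by default). Monte
Carlo p = (1 + #{null ≥ observed}) / (n_perm + 1); each tail is tested at
α = 0.025. Undefined or zero-variance points are excluded from clustering
entirely.

Calibration (computed in the acceptance suite): over 200 null replicates
(12 subjects, 8 channels, 10 × 20 bins, 500 permutations) the per-tail
familywise error rate's 95% CI contains 0.025; a +1 dB effect over 3
neighbouring channels × 8–12 Hz × −500…0 ms with unit-SD subject noise
(n = 20) is recovered with ≥ 50% spatial overlap in ≥ 90% of replicates.

## Decoding

Features: raw power averaged over the strictly pre-stimulus time bins of
−1000…−200 ms, one value per channel × frequency (2–60 Hz), classes
equalized by random subsampling so chance is exactly 0.5. Classifier:
linear SVM; `C ∈ {10⁻², …, 10²}` chosen by stratified 5-fold grid search
on the training set only (ties resolve to the smallest C); trained on
Experiment 1, tested exactly once on Experiment 2 of the same subject.
`mode="per_frequency"` fits one decoder per frequency and applies the
binomial mask / peak-accuracy logic across frequencies;
`mode="single"` (default) yields one accuracy.

Significance: exact one-sided binomial p = P(K ≥ k | n_test, 0.5)
(verified against arbitrary-precision tail summation for all n ≤ 100);
mask at p ≤ 0.05; peak accuracy is the masked maximum, falling back to the
global maximum; the cohort of peaks is compared to 0.5 with a one-sample
*t*. Chance calibration uses the randomized probability integral
transform of the binomial counts, which is exactly Uniform(0, 1) under H0
even with varying n_test, so a Kolmogorov–Smirnov test applies.

Group level: leave-one-participant-out — per subject and experiment, each
feature is z-transformed across that subject's trials before pooling; the
held-out subject's Experiment-2 trials are tested once.

Previous-rating control: trials whose previous rating is neutral, missed
or undefined are removed; decoder A trains on previous-trial labels and is
scored on the same trials against their current labels; decoder B is a
stratified 5-fold × 4-repeat CV on current labels; peak accuracies are
compared with a paired *t* over subjects.

## Behavior

Negativity bias = 100 · n_negative / (n_negative + n_positive +
n_neutral); a neutral response is a logged rating and counts in the
denominator, a missed response does not. Between-experiment comparison:
paired *t* over subjects usable in both experiments (all-zero differences
give t = 0 exactly; constant nonzero differences have undefined *t* and
are flagged NaN). Questionnaire association: Pearson *r* of the bias with
BDI-2, STAI-S and STAI-T. Participants need ≥ 10 trials per rating class
per experiment to be included.

## Synthetic generator: model and scope

Each trial of each channel is the sum of

- **1/f^β background**: Gaussian noise spectrally shaped by FFT, exactly
  unit variance per trial and channel (β = 1, amplitude 1 µV by default);
- **ongoing alpha**: a 10 Hz sinusoid with Rayleigh-distributed amplitude
  (mean power 0.5 µV²) and uniform phase per trial and channel;
- **the effect**: an induced 8–12 Hz burst under a Hann envelope in
  −500…0 ms at CP3/CP5/C3, coherent across the effect channels within a
  trial, with random phase and a per-trial frequency drawn uniformly from
  the band.

Burst power is `burst_power` (8 µV²) on positive-rated trials and
`10^(effect_size_db/10)` times that on negative-rated trials, with a 3 dB
log-normal trial-to-trial jitter. `effect_size_db` is a **free simulation
parameter** — the effect contrast of real data of this kind is not known
in dB. The defaults were fixed at design time: `burst_power = 8` makes
the burst dominate the 0.5 µV²-mean alpha floor so the realized contrast
tracks the nominal one; at `effect_size_db = 3` the single-channel
band-power contrast has Cohen's d ≈ 0.8, and ≈ 1 at 4 dB (the setting
used for the d ≈ 1 decoding-sensitivity check).

Ratings are i.i.d. with P(negative) = the subject's bias (so the bias
estimator is unbiased by construction), P(neutral) = 0.05; the bias is
drawn per subject from a normal truncated to [0.05, 0.95] with means
0.55 (Experiment 1) and 0.65 (Experiment 2) and SD 0.12, the same latent
deviation shifted between experiments so biases correlate within subject.
Subjects with a stronger bias carry a stronger effect
(`effect_bias_coupling_db = 6` dB per unit bias), giving the
bias-correlation analysis signal to find. The Experiment-2 effect
channels/band can be overridden to probe cross-decoding transfer
specificity.

Determinism: every subject's streams derive from
`SeedSequence(seed, spawn_key=(subject, stream))`, so a subject's data is
bit-identical regardless of cohort size, and the full pipeline is
byte-identical across reruns of the same configuration.

### Limitations

- The generator is a statistical stand-in, not a biophysical model: no
  volume conduction beyond what the common average reference induces, no
  evoked response, no artifacts, no autocorrelated behavior.
- The effect is stationary across trials (up to jitter); real
  pre-stimulus states fluctuate more richly.
- The questionnaire scores are drawn independently of the bias, so
  questionnaire correlations are null by construction.
- EDF import shares all logic with the BrainVision path but is untested
  against real EDF files in this repository (no EDF writer available in
  the test environment).

## Numerical choices

- Spectrogram kernels are precomputed cosine/sine matrices contracted by
  `einsum` in trial chunks; equality with the direct DFT is oracle-tested.
- Permutation t-maps are vectorized over randomizations using the
  sign-flip identity var = (Σd² − n·mean²)/(n − 1), where Σd² is
  invariant under sign flips.
- Connected components use precomputed flat neighbour lists and an
  explicit stack, oracle-tested against `scipy.sparse.csgraph`.
- All p-values from permutations use the add-one rule, so the smallest
  attainable p is 1/(n_perm + 1) and tests are never anti-conservative by
  zero counts.
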