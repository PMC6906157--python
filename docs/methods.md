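# Methods

## Model

The analysis treats perception during a balanced two-alternative
categorization task as approximate Bayesian inference. On each trial a
stimulus with true category ν ∈ {1, 2} evokes a category perception,
represented in the brain by an internal state μ. The *recognition
distribution* Q(ν | μ, m) is the brain's (implicit) posterior over true
categories given its perception state; the *generative model*
P(o, ν | M) of an ideal observer maps optimal category perceptions o
one-to-one onto categories with equal priors:

    P(o, ν | M) = δ_oν · 0.5.

The free-energy difference of state (o, μ), in nats, is

    ΔF(o, μ) = Σ_ν Q(ν|μ) ln Q(ν|μ) − Σ_ν Q(ν|μ) ln P(o, ν|M),

with 0·ln 0 := 0 in the entropy term. The four state values are summed
to ΔF_Total and collapsed into matched (o = μ) and mismatched (o ≠ μ)
means. By Jensen's inequality ΔF ≥ −ln(max_ν P(o, ν)) ≥ ln 2 up to
ε-order terms, so all reported differences are positive.

**ε-regularization.** The δ-model's off-diagonal zeros make the cross
term infinite whenever Q places any mass on the non-matching category.
Exact zeros are therefore replaced by a configurable ε (default 1e-3,
exposed as `epsilon` everywhere and recorded in every result). With
recognition rows near [0.67, 0.33], ε = 1e-3 puts matched states near
2.1 nats, mismatched near 4.2, and totals near 12.7 — the scale on
which such estimates are reported. Because ΔF_Total =
−4·H(Q_diag) − 2 ln(0.5 ε) for symmetric Q, the choice of ε shifts the
total by an additive constant and does not affect orderings or
correlations.

**Bounded rationality.** For Boltzmann-type distributions the decision
trade-off takes the form −ΔF(q) = Σ q U − (1/ζ) Σ q ln(q/p0), with the
resource (inverse-temperature) parameter ζ; the magnitude of the
difference shrinks as ζ grows. `free_energy.boltzmann_curve` evaluates
this relationship on a ζ grid.

## Estimating the recognition distribution

Trials are screened (non-responses, artifact epochs) and the remaining
epochs pass through: peak-to-peak artifact scoring (default 150 μV) →
bad-channel interpolation → average reference → zero-phase band-pass →
baseline correction.

*Filter realization.* The 30 Hz upper edge is a forward-backward
4th-order Butterworth. A genuine 0.1 Hz lower edge is unrealizable on
1.2 s epochs — an FIR with that transition would need tens of
thousands of taps and a recursive filter's ~10 s settling time cannot
be initialized from 307 samples — so the sub-0.1 Hz band, which over
1.2 s is spanned by a constant plus a linear drift to excellent
approximation, is removed by per-epoch linear detrending. The realized
response is zero-phase, exact at DC, flat at 10 Hz, and > 40 dB down
at 60 Hz.

*Interpolation.* Channel positions are the idealized spherical 10/5
montage coordinates; a bad channel is replaced by the inverse-distance
weighted mean of its k = 4 nearest good neighbors. This is a
deliberate simplification of spherical-spline interpolation; for the
smooth fields simulated here the two agree to within a few percent.

*CSP features.* Channel data are PCA-whitened on the pooled
(trial-averaged, trace-normalized) covariance of the post-stimulus
window (0–1000 ms), retaining components that explain 99% of pooled
variance; the retained rank defines N_rank. Whitening stands in for
the ICA decorrelation step sometimes used before CSP — its purpose
here is covariance conditioning, which whitening achieves
deterministically. CSP filters solve Σ₁w = λ(Σ₁+Σ₂)w on the two
*behaviorally reported* perception classes; all N_rank filters feed
the per-trial feature vector f_i = log(var(Z_i)/Σ var(Z_j)), which is
scale-invariant and satisfies Σ exp(f_i) = 1.

*Classification.* K-means (k = 2, random centroid initialization)
indexes the perception state per trial; the cluster→perception
bijection maximizing agreement with the reported decisions is chosen
(ties map cluster 0 to perception 1). An RBF-kernel SVM is trained on
the true categories under stratified 10-fold CV; held-out posteriors
come from a sigmoid (Platt-style) link fitted to training-fold decision
values, so every trial receives exactly one test posterior per repeat.
Averaging held-out posteriors within perception groups gives one Q
estimate; fresh K-means initializations and fold partitions are drawn
per repeat (200 by default; cohort-scale analyses here use 20–50) and
the repeat estimates averaged. Hyperparameters (σ, box ∈ [1e-3, 1e5],
log-uniform) are tuned once per participant by random search
minimizing stratified 10-fold CV misclassification (budget 30). Tuning
on all trials before the repeats is a mild optimism source, as is
fitting the CSP transform outside the CV loop; both are properties of
the estimation design this package reproduces, and the synthetic
chance-floor tests bound their practical impact.

## Resource parameter ζ

Utilities are U(d_i|m) = ln P(d_i|m) with P(d_i|m) =
Σ_j P(d_i|ν_j,m)·0.5 from the empirical decision-given-category
confusion; per trial the utility is non-zero only for the decision
actually made, giving the regressor x_t = U(d1)·1[d=1] − U(d2)·1[d=2].
Because x_t's sign is a deterministic function of the decision, a
regression of the decision on x_t is perfectly separable and its MLE
diverges; ζ is therefore estimated by intercept-free logistic
regression of the *true-category* indicator 1[ν=1] on x_t. Under
balanced decisions this estimator has the closed form ζ̂ =
−logit(p_correct)/ln 2, which the tests use as an independent oracle;
fitted group values land within a few hundredths of the printed group
means when reconstructed from group accuracies. Above-chance accuracy
yields ζ̂ < 0, and higher accuracy yields larger |ζ̂|, so the
more-accurate task shows the more negative ζ. Perfect accuracy makes
the estimate diverge and raises an informative error.

## Synthetic cohort

The generator emulates exactly the structure the estimator assumes and
nothing more:

- **Behavior**: perception μ_t = ν_t with probability p (per-participant
  p drawn uniformly in p ± 0.15, clipped to [0.52, 0.95]; task defaults
  p_II = 0.72, p_RB = 0.65 reproduce the II > RB accuracy ordering);
  decisions lapse with probability 0.02; non-responses at 1%;
  log-normal RTs with a lower median on correct trials (470 vs 518 ms).
- **EEG**: 32 channels (up to 72), 256 Hz, −200…1000 ms. Background
  noise has a 1/f amplitude spectrum per source and is spatially mixed
  through a random orthogonal basis with power-law (k^−1.5) gains,
  giving the steep spatial eigen-spectrum of real EEG — a few dominant
  large-scale components and a long weak tail. The perception state is
  carried by one of two fixed orthogonal smooth unit-norm topographies
  times a Hann waveform on 300–700 ms; `snr` scales its amplitude
  against the background RMS (snr = 0 carries no information).
  Artifact trials (5%) receive a 500 μV slow deflection.
- **Workload**: score = clip(0.6 + 0.1·ζ_true + N(0, 0.03), 0, 1), so a
  positive slope yields a positive workload–ζ cohort correlation and
  scores near 0.5 for ζ near −1.

What the generator does *not* emulate: ocular/muscle artifact
morphology, biophysical source geometry, non-stationarity across the
session, or any genuine perceptual process behind p. Passing tests
therefore validate the estimation machinery under the assumed
statistical structure, not the neurophysiological claims themselves.

## Statistics

ERP = trial mean per channel/time; GFP = population standard deviation
of the ERP across channels per time point. Paired waveform contrasts
use pointwise t-tests with max-|t| familywise correction, resampling by
within-participant sign flips of difference waveforms. Permutation
repeated-measures ANOVA (one-way, and fully-within two-way with each
effect tested against its own subject-interaction error term) permutes
condition labels within participant; observed F and partial η² come
from the standard decomposition; p-values use +1 smoothing. Pearson
correlations are tested by shuffling one variable (5000 draws by
default); families of correlation p-values are corrected by
Benjamini–Hochberg FDR at q = 0.05.

## Numerical and design choices

- Seeds: every draw descends from one master seed via
  `SeedSequence.spawn` (master → participant → stage → repeat); reruns
  are bit-identical. No on-disk caching of intermediates — deterministic
  regeneration is cheap at these problem sizes.
- Degenerate inputs raise informative errors rather than returning
  NaNs: all-flagged artifact sets, identical feature vectors, empty
  perception groups (a repeat is discarded; > 10% discarded aborts),
  zero-variance trials, perfect accuracy in the ζ fit.
- Problem sizes used in the shipped tests: 240 trials, 32 channels per
  participant; 50 classifier repeats for the SNR battery and 20 for the
  40-participant cohort analysis. These sizes already put the K-means
  agreement (~0.98) and the recognition diagonal (≈ behavioral p)
  in the regime where the cohort-level free-energy/ζ correlation is
  strongly negative (r ≈ −0.97 at snr 2).
- The eigenvalue convention reports λ_i = class-1 variance share in
  (0, 1), sorted by discriminability max(λ, 1−λ); filters are
  normalized so wᵀ(Σ₁+Σ₂)w = 1.

## Known limitations

- The ε-regularization of the δ-generative model is a convention; only
  ε-invariant quantities (orderings, correlations) should be compared
  across analyses that might choose ε differently.
- CSP fitting outside the CV loop and single-shot hyperparameter tuning
  leak a small amount of information into held-out posteriors; at the
  synthetic study conditions this inflates the recognition diagonal by
  at most a few percent (bounded by the snr = 0 chance-floor test).
- The inverse-distance interpolation and the detrending realization of
  the 0.1 Hz edge are simplifications appropriate for epoch-level
  analysis; continuous-recording pipelines should filter before
  epoching.
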