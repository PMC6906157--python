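# brainfe

Estimation of **global brain free-energy differences** from single-trial
EEG recorded during two-category visual decisions, together with the
behavioral **bounded-rationality resource parameter ζ** and the
permutation statistics that relate the two across a cohort.

## The problem

During a two-alternative Gabor categorization task (an
information-integration task with a diagonal category boundary, and a
rule-based task with a verbalizable conjunction rule), the brain forms a
*category perception* μ of the true stimulus category ν. Under the
free-energy account of perception, the quality of that inference is
measured by the variational free energy of the brain's *recognition
distribution* Q(ν | μ, m) relative to an ideal observer's generative
model P(o, ν | M):

```
ΔF(o, μ) = Σ_ν Q(ν|μ,m) ln Q(ν|μ,m) − Σ_ν Q(ν|μ,m) ln P(o,ν|M)   [nats]
```

For a noise-free ideal categorizer the generative model is diagonal,
P(o, ν | M) = δ_oν · 0.5; exact off-diagonal zeros are replaced by a
small ε (default 1e-3) so the cross term stays finite. The four
per-state differences are summed to a total ΔF_Total and collapsed into
matched (o = μ) and mismatched (o ≠ μ) means.

The package estimates Q(ν | μ, m) from EEG alone:

1. **Preprocessing** — artifact scoring, bad-channel interpolation,
   average reference, zero-phase 0.1–30 Hz band-pass, baseline
   correction on −200…1000 ms epochs at 256 Hz.
2. **CSP features** — PCA whitening, then common spatial patterns on
   the two behaviorally reported perception classes; per-trial features
   are log variance shares `f_i = log(var(Z_i) / Σ_j var(Z_j))`.
3. **Recognition estimate** — K-means (k = 2) indexes the perception
   state per trial; an RBF-kernel SVM with sigmoid-calibrated
   posteriors, trained on the true categories under stratified 10-fold
   CV, yields held-out posteriors which are averaged within perception
   groups. Both classifications are repeated (200× by default) and
   averaged.

Independently, ζ is fitted from behavior with a softmax decision model,
`P(d1) = 1/(1 + exp(−ζ (U(d1|m) − U(d2|m))))` with utilities
`U(d_i|m) = ln P(d_i|m)`, by intercept-free logistic regression; under
balanced decisions the estimate has the closed form
`ζ̂ = −logit(p_correct)/ln 2`. Across participants ΔF_Total and ζ are
negatively coupled — more allocated processing resources, smaller
free-energy differences.

A first-class **synthetic cohort generator** produces behavior, EEG
epochs (two perception-specific scalp topographies on spatially
correlated 1/f noise at configurable SNR) and workload scores coupled
to ζ, so the whole pipeline is testable without any recordings.

## Worked example

```python
import numpy as np
from brainfe.synthetic import CohortConfig, simulate_participant
from brainfe.pipeline import run_participant

cfg = CohortConfig(n_trials=240, p=0.7, snr=2.0, n_channels=32)
trials, epochs, workload, p_i, zeta_true = simulate_participant(
    cfg, np.random.SeedSequence(5))
res = run_participant(trials, epochs, n_repeats=20, rng_seed=7)
print(np.round(res.recognition.Q, 3))
print(round(res.free_energy.dF_total, 3),
      round(res.free_energy.matched_mean, 3),
      round(res.free_energy.mismatched_mean, 3))
print(round(res.softmax.zeta, 3))
```

prints

```
[[0.667 0.333]
 [0.331 0.669]]
12.659 2.122 4.207
-0.887
```

The recognition matrix places ~0.67 probability on the correct category
given the decoded perception state (this participant perceives correctly
with probability p ≈ 0.67); matched states carry ~2.1 nats, mismatched
~4.2 nats, totalling ~12.7 nats; the behavioral resource parameter is
negative, as expected for above-chance accuracy.

The command-line entry point wraps the same functions:

```
brainfe simulate --task II --seed 0 --out cohort_II
brainfe fit cohort_II/participant_000 --repeats 200
brainfe analyze --seed 0 --out report
```

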