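"""Synthetic cohort generator: behavior, EEG epochs, workload scores.

The generator emulates the statistical structure the analysis assumes:

* a latent category *perception* ``mu`` that matches the true category
  ``nu`` with probability ``p`` (perceptual accuracy);
* a decision ``d`` that follows the perception except for an
  occasional lapse, plus rare non-responses;
* EEG epochs in which the perception state is carried by one of two
  fixed smooth scalp topographies riding on spatially correlated 1/f
  background noise, at a configurable signal-to-noise amplitude ratio;
* a per-participant subjective workload score linearly coupled to the
  participant's generative resource parameter zeta.

Everything is deterministic given the master seed; per-participant and
per-stage seeds are spawned hierarchically from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from brainfe.preprocess import EpochSet, channel_positions, default_channel_names
from brainfe.resource_model import zeta_closed_form

__all__ = [
    "CohortConfig",
    "simulate_behavior",
    "simulate_epochs",
    "simulate_workload",
    "simulate_participant",
    "simulate_cohort",
]


@dataclass
class CohortConfig:
    """Study-condition parameters for one synthetic task cohort.

    ``p`` is the probability that the latent perception equals the true
    category; defaults mirror a two-task design where the
    information-integration task is performed more accurately
    (p = 0.72) than the rule-based task (p = 0.65).  ``p_spread`` is
    the half-width of the uniform participant-level variation around
    ``p``.  ``snr`` is the perception-signal to background-noise
    amplitude ratio of the injected EEG component.
    """

    n_participants: int = 40
    n_trials: int = 240
    p: float = 0.72
    p_spread: float = 0.15
    lapse: float = 0.02
    snr: float = 2.0
    n_channels: int = 32
    sfreq: float = 256.0
    epoch_window_ms: tuple = (-200.0, 1000.0)
    nonresponse_rate: float = 0.01
    artifact_rate: float = 0.05
    workload_intercept: float = 0.6
    workload_slope: float = 0.1
    workload_noise_sd: float = 0.03
    master_seed: int = 0

    def __post_init__(self):
        if not 0 < self.p < 1:
            raise ValueError("p must be in (0, 1)")
        if not 0 <= self.lapse < 1:
            raise ValueError("lapse must be in [0, 1)")
        if self.snr < 0:
            raise ValueError("snr must be non-negative")
        if self.n_channels < 4:
            raise ValueError("n_channels must be >= 4")


def simulate_behavior(
    true_categories,
    p: float,
    lapse: float = 0.0,
    rng_seed: int = 0,
    nonresponse_rate: float = 0.0,
    rt_median_correct_ms: float = 470.0,
    rt_median_incorrect_ms: float = 518.0,
    rt_sigma: float = 0.25,
) -> pd.DataFrame:
    """Simulate perceptions, decisions and reaction times per trial.

    The perception equals the true category with probability ``p``; the
    decision equals the perception with probability ``1 - lapse``.
    Reaction times are lognormal with a lower median on correct trials.
    Expected behavioral accuracy is ``p (1 - lapse) + (1 - p) lapse``.

    Returns a trial table with columns ``trial, true_category, mu_true,
    decision, responded, correct, rt_ms, artifact`` (decision 0 encodes
    a non-response; ``artifact`` is filled by the epoch simulator).
    """
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    if not 0 <= lapse < 1:
        raise ValueError("lapse must be in [0, 1)")
    nu = np.asarray(true_categories, dtype=int)
    if not np.isin(nu, (1, 2)).all():
        raise ValueError("true categories must be in {1, 2}")
    rng = np.random.default_rng(rng_seed)
    n = len(nu)
    mu = np.where(rng.uniform(size=n) < p, nu, 3 - nu)
    d = np.where(rng.uniform(size=n) < 1.0 - lapse, mu, 3 - mu)
    responded = rng.uniform(size=n) >= nonresponse_rate
    d = np.where(responded, d, 0)
    correct = (d == nu) & responded
    medians = np.where(correct, rt_median_correct_ms, rt_median_incorrect_ms)
    rt = np.exp(np.log(medians) + rt_sigma * rng.standard_normal(n))
    rt = np.where(responded, rt, np.nan)
    return pd.DataFrame(
        {
            "trial": np.arange(n),
            "true_category": nu,
            "mu_true": mu,
            "decision": d,
            "responded": responded,
            "correct": correct,
            "rt_ms": rt,
            "artifact": np.zeros(n, dtype=bool),
        }
    )


def _one_over_f_noise(rng, n_series: int, n_samples: int, sfreq: float) -> np.ndarray:
    """Gaussian series with a 1/f amplitude spectrum (floored at 1 Hz)."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sfreq)
    amp = 1.0 / np.maximum(freqs, 1.0)
    amp[0] = 0.0  # no DC
    spec = amp * (
        rng.standard_normal((n_series, len(freqs)))
        + 1j * rng.standard_normal((n_series, len(freqs)))
    )
    x = np.fft.irfft(spec, n=n_samples, axis=-1)
    x /= x.std(axis=-1, keepdims=True) + 1e-30
    return x


def _smooth_topography(rng, pos: np.ndarray, scale: float = 0.5) -> np.ndarray:
    """Random spatially smooth unit-norm scalp pattern."""
    d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
    K = np.exp(-d2 / (2 * scale**2))
    a = K @ rng.standard_normal(len(pos))
    return a / np.linalg.norm(a)


def simulate_epochs(
    trials: pd.DataFrame,
    cfg: CohortConfig,
    rng_seed: int = 0,
    noise_rms_uv: float = 10.0,
) -> EpochSet:
    """Simulate EEG epochs whose topography encodes the perception state.

    Each epoch is spatially correlated 1/f background noise plus a
    perception-specific component: one of two fixed orthogonal smooth
    unit-norm topographies times an ERP-like waveform supported on
    300-700 ms, with amplitude ``cfg.snr`` times the background RMS
    (per channel).  A fraction ``cfg.artifact_rate`` of trials receive
    a large slow deflection emulating movement artifacts and are marked
    in the returned table's ``artifact`` column.
    """
    if cfg.snr < 0:
        raise ValueError("snr must be non-negative")
    rng = np.random.default_rng(rng_seed)
    n_trials = len(trials)
    n_ch = cfg.n_channels
    n_samples = int(round((cfg.epoch_window_ms[1] - cfg.epoch_window_ms[0]) / 1000.0 * cfg.sfreq))
    times = (np.arange(n_samples) / cfg.sfreq) * 1000.0 + cfg.epoch_window_ms[0]
    names = default_channel_names(n_ch)
    pos = channel_positions(names)

    # spatial mixing: random orthogonal basis with power-law decaying
    # gains, giving the steep spatial eigen-spectrum of real EEG (a few
    # dominant large-scale components plus a long weak tail)
    Q, _ = np.linalg.qr(rng.standard_normal((n_ch, n_ch)))
    gains = np.arange(1, n_ch + 1, dtype=float) ** -1.5
    mix = Q * gains

    # two distinct perception topographies (orthogonalized)
    a1 = _smooth_topography(rng, pos)
    a2 = _smooth_topography(rng, pos)
    a2 = a2 - (a2 @ a1) * a1
    a2 /= np.linalg.norm(a2)
    topos = {1: a1, 2: a2}

    # ERP-like waveform: Hann bump on 300-700 ms, unit peak
    wave = np.zeros(n_samples)
    bump = (times >= 300.0) & (times <= 700.0)
    wave[bump] = np.hanning(bump.sum())

    data = np.empty((n_trials, n_ch, n_samples))
    for t in range(n_trials):
        src = _one_over_f_noise(rng, n_ch, n_samples, cfg.sfreq)
        noise = mix @ src
        noise *= noise_rms_uv / (noise.std() + 1e-30)
        amp = cfg.snr * noise_rms_uv * np.sqrt(n_ch) * rng.uniform(0.8, 1.2)
        mu = int(trials["mu_true"].iloc[t])
        data[t] = noise + amp * np.outer(topos[mu], wave)

    artifact = rng.uniform(size=n_trials) < cfg.artifact_rate
    if artifact.any():
        slow = np.sin(np.linspace(0, np.pi, n_samples))
        for t in np.where(artifact)[0]:
            ch = rng.integers(n_ch)
            data[t, ch] += 500.0 * slow
    trials = trials.copy()
    trials["artifact"] = artifact

    epochs = EpochSet(
        data=data,
        sfreq=cfg.sfreq,
        times=times,
        channel_names=names,
        reference="raw",
    )
    epochs.trials = trials  # convenience back-reference
    return epochs


def simulate_workload(
    zeta_true,
    slope: float = 0.1,
    noise_sd: float = 0.03,
    intercept: float = 0.6,
    rng_seed: int = 0,
):
    """Workload scores linearly coupled to the resource parameter.

    score = clip(intercept + slope * zeta + noise, 0, 1).  With the
    defaults and zeta near -1, scores land near 0.5; a positive slope
    yields a positive cohort correlation between workload and zeta.
    """
    if not np.isfinite(slope):
        raise ValueError("slope must be finite")
    z = np.atleast_1d(np.asarray(zeta_true, dtype=float))
    rng = np.random.default_rng(rng_seed)
    scores = intercept + slope * z + noise_sd * rng.standard_normal(len(z))
    return np.clip(scores, 0.0, 1.0)


def _participant_p(cfg: CohortConfig, rng) -> float:
    lo = max(0.52, cfg.p - cfg.p_spread)
    hi = min(0.95, cfg.p + cfg.p_spread)
    return float(rng.uniform(lo, hi))


def simulate_participant(cfg: CohortConfig, seed_seq: np.random.SeedSequence):
    """One participant: (trial table, epochs, workload score, p, zeta_true)."""
    s_p, s_beh, s_eeg, s_wl = seed_seq.spawn(4)
    rng = np.random.default_rng(s_p)
    p_i = _participant_p(cfg, rng)
    nu = rng.permutation(np.repeat([1, 2], cfg.n_trials // 2))
    trials = simulate_behavior(
        nu,
        p=p_i,
        lapse=cfg.lapse,
        rng_seed=s_beh,
        nonresponse_rate=cfg.nonresponse_rate,
    )
    epochs = simulate_epochs(trials, cfg, rng_seed=s_eeg)
    acc = p_i * (1 - cfg.lapse) + (1 - p_i) * cfg.lapse
    zeta_true = zeta_closed_form(acc)
    workload = float(
        simulate_workload(
            zeta_true,
            slope=cfg.workload_slope,
            noise_sd=cfg.workload_noise_sd,
            intercept=cfg.workload_intercept,
            rng_seed=s_wl,
        )[0]
    )
    return epochs.trials, epochs, workload, p_i, zeta_true


def simulate_cohort(cfg: CohortConfig):
    """Generator over participants of one task cohort.

    Yields ``(participant_id, trials, epochs, workload, p, zeta_true)``
    lazily so cohorts never hold all epoch arrays in memory at once.
    """
    root = np.random.SeedSequence(cfg.master_seed)
    for i, ss in enumerate(root.spawn(cfg.n_participants)):
        trials, epochs, workload, p_i, zeta_true = simulate_participant(cfg, ss)
        yield i, trials, epochs, workload, p_i, zeta_true
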