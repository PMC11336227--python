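"""Synthetic two-experiment EEG cohorts with a pre-stimulus valence effect.

The generator emulates the statistical structure the downstream analysis
assumes: 1/f background activity per channel, ongoing alpha oscillations,
and a band-limited oscillatory burst over left centro-parietal channels in
the pre-stimulus window whose power is larger (by ``effect_size_db``) on
trials the subject later rates as negative.  Ratings follow a per-subject
negativity bias drawn from a truncated normal, so the cohort shows the wide
between-subject spread the bias-correlation analysis requires.

Each subject performs two experiments: many repeated artificial-face trials
(Experiment 1, default 210) and 68 single-presentation natural-face trials
(Experiment 2).  The injected effect is shared across experiments unless
explicitly overridden (e.g. to probe cross-decoding transfer specificity).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import stats

from .epochs import NO_PREVIOUS, EpochSet
from .montage import Montage, load_acticap60

__all__ = [
    "SimConfig",
    "SubjectData",
    "pink_noise",
    "oscillatory_burst",
    "simulate_behavior",
    "simulate_subject",
    "simulate_cohort",
    "simulate_difference_maps",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort.

    The defaults mirror the study conditions: 500 Hz sampling, -2000..+2000
    ms epochs, 210 / 68 trials in the two experiments, an 8-12 Hz effect
    over CP3/CP5/C3 in the 500 ms before face onset, and experiment-wise
    mean negativity biases of 55% and 65% with a 0.12 between-subject SD.
    ``effect_size_db`` is a free simulation parameter (the study does not
    report the contrast in dB); the 3 dB default together with a 3 dB
    trial-to-trial power jitter yields a single-feature effect size of
    roughly d = 1.
    """

    n_subjects: int = 36
    n_trials_exp1: int = 210
    n_trials_exp2: int = 68
    sampling_rate: float = 500.0
    epoch_window: tuple = (-2000.0, 2000.0)
    channels: tuple | None = None  # None -> full 60-channel montage
    bias_mean_exp1: float = 0.55
    bias_mean_exp2: float = 0.65
    bias_sd: float = 0.12
    bias_range: tuple = (0.05, 0.95)
    neutral_prob: float = 0.05
    missed_prob: float = 0.0
    effect_channels: tuple = ("CP3", "CP5", "C3")
    effect_band: tuple = (8.0, 12.0)
    effect_window: tuple = (-500.0, 0.0)
    effect_size_db: float = 3.0
    effect_channels_exp2: tuple | None = None  # None -> same as exp1
    effect_band_exp2: tuple | None = None
    effect_bias_coupling_db: float = 6.0  # extra dB per unit of subject bias
    burst_power: float = 8.0  # uV^2, positive-class burst power
    trial_power_sd_db: float = 3.0  # per-trial burst power jitter (dB)
    alpha_power: float = 0.5  # uV^2, ongoing 10 Hz activity
    alpha_freq: float = 10.0
    noise_exponent: float = 1.0
    noise_amplitude: float = 1.0  # uV, SD of the 1/f background
    post_effect: bool = False
    post_effect_window: tuple = (500.0, 1500.0)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.bias_mean_exp1 <= 1.0 or not 0.0 <= self.bias_mean_exp2 <= 1.0:
            raise ValueError("bias means must be probabilities")
        if not 0.0 <= self.neutral_prob < 1.0:
            raise ValueError("neutral_prob must be in [0, 1)")
        lo, hi = self.epoch_window
        wlo, whi = self.effect_window
        if not (lo <= wlo < whi <= hi):
            raise ValueError("effect_window must lie within epoch_window")
        blo, bhi = self.effect_band
        if not (2.0 <= blo < bhi <= 120.0):
            raise ValueError("effect_band must lie within 2-120 Hz")
        if not np.isfinite(self.noise_exponent) or not 0.0 <= self.noise_exponent <= 2.0:
            raise ValueError("noise_exponent must be finite and in [0, 2]")

    def montage(self) -> Montage:
        full = load_acticap60()
        if self.channels is None:
            return full
        return full.subset(self.channels)


@dataclass
class SubjectData:
    """One simulated participant: both experiments plus a behavior record."""

    exp1: EpochSet
    exp2: EpochSet
    behavior: dict


# ---------------------------------------------------------------------------
# primitives


def _pink_noise_nd(shape, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean, unit-variance 1/f^beta noise along the last axis."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n)
    scale = np.empty_like(freqs)
    scale[0] = 0.0  # no DC component
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * scale, n=n, axis=-1)
    x -= x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    return x / sd


def pink_noise(n_samples: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """One zero-mean, unit-variance series with a 1/f^beta power spectrum.

    ``exponent`` = 0 gives white noise, 1 pink, 2 brown.  Variance is
    exactly 1 by explicit normalization.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if not np.isfinite(exponent) or not 0.0 <= exponent <= 2.0:
        raise ValueError("exponent must be finite and in [0, 2]")
    return _pink_noise_nd((n_samples,), exponent, rng)


def oscillatory_burst(freq: float, amplitude: float, window, times,
                      phase: float = 0.0) -> np.ndarray:
    """Sinusoid under a Hann envelope supported only inside ``window`` (ms).

    Zero outside the window; ``times`` is the epoch's ms axis.  The Hann
    envelope rises from and returns to exactly zero at the window edges.
    """
    times = np.asarray(times, dtype=float)
    lo, hi = float(window[0]), float(window[1])
    if lo < times[0] or hi > times[-1] or lo >= hi:
        raise ValueError("burst window must lie within the time axis")
    out = np.zeros_like(times)
    inside = (times >= lo) & (times <= hi)
    t = times[inside]
    envelope = 0.5 * (1.0 - np.cos(2.0 * np.pi * (t - lo) / (hi - lo)))
    out[inside] = amplitude * envelope * np.sin(2.0 * np.pi * freq * t / 1000.0 + phase)
    return out


def simulate_behavior(n_trials: int, bias_prob: float, neutral_prob: float,
                      rng: np.random.Generator, missed_prob: float = 0.0) -> np.ndarray:
    """I.i.d. valence ratings with P(negative) = ``bias_prob``.

    The expected fraction of negative labels among all ratings equals
    ``bias_prob``; positive fills the remainder after neutral (and missed).
    """
    if not 0.0 <= bias_prob <= 1.0 or not 0.0 <= neutral_prob < 1.0:
        raise ValueError("probabilities must be valid")
    if bias_prob + neutral_prob + missed_prob > 1.0 + 1e-12:
        raise ValueError("bias_prob + neutral_prob + missed_prob must be <= 1")
    p = [bias_prob, 1.0 - bias_prob - neutral_prob - missed_prob,
         neutral_prob, missed_prob]
    labels = np.array(["negative", "positive", "neutral", "missed"])
    return rng.choice(labels, size=n_trials, p=p)


# ---------------------------------------------------------------------------
# subjects and cohorts


def _subject_rng(seed: int, subject_index: int, stream: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(subject_index, stream))
    return np.random.default_rng(ss)


def _subject_bias(config: SimConfig, subject_index: int) -> tuple:
    """Per-subject negativity bias for both experiments.

    The Experiment-1 bias is drawn from a normal truncated to
    ``bias_range``; the Experiment-2 bias is the same latent tendency
    shifted by the difference of the experiment means (clipped), so biases
    are correlated across experiments within subject.
    """
    rng = _subject_rng(config.seed, subject_index, stream=0)
    lo, hi = config.bias_range
    a = (lo - config.bias_mean_exp1) / config.bias_sd
    b = (hi - config.bias_mean_exp1) / config.bias_sd
    b1 = float(stats.truncnorm.rvs(a, b, loc=config.bias_mean_exp1,
                                   scale=config.bias_sd, random_state=rng))
    b2 = float(np.clip(b1 + (config.bias_mean_exp2 - config.bias_mean_exp1), lo, hi))
    return b1, b2


def _jitter_mean_factor(sd_db: float) -> float:
    """E[10^(X/10)] for X ~ N(0, sd_db): mean power inflation by the jitter."""
    s = sd_db * np.log(10.0) / 10.0
    return float(np.exp(s * s / 2.0))


def _simulate_epochs(config: SimConfig, montage: Montage, n_trials: int,
                     bias_prob: float, effect_db: float, effect_channels,
                     effect_band, subject_id: int, experiment: int,
                     rng: np.random.Generator) -> EpochSet:
    lo, hi = config.epoch_window
    dt = 1000.0 / config.sampling_rate
    times = np.arange(lo, hi + dt / 2.0, dt)
    n_samples = len(times)
    n_channels = montage.n_channels
    try:
        eff_idx = [montage.index(c) for c in effect_channels]
    except KeyError as exc:
        raise KeyError(f"effect channel not in montage: {exc}") from exc

    labels = simulate_behavior(n_trials, bias_prob, config.neutral_prob,
                               rng, config.missed_prob)

    data = config.noise_amplitude * _pink_noise_nd(
        (n_trials, n_channels, n_samples), config.noise_exponent, rng)

    # ongoing alpha at every channel: Rayleigh amplitude, random phase
    amp = rng.rayleigh(scale=np.sqrt(config.alpha_power / 2.0),
                       size=(n_trials, n_channels, 1))
    phase = rng.uniform(0.0, 2.0 * np.pi, size=(n_trials, n_channels, 1))
    carrier = 2.0 * np.pi * config.alpha_freq * times / 1000.0
    data += amp * np.sin(carrier[None, None, :] + phase)

    # class-dependent band-limited burst at the effect channels: amplitude
    # modulation of an induced (random-phase) oscillation
    ratio = 10.0 ** (effect_db / 10.0)
    p_pos = config.burst_power
    p_neg = p_pos * ratio
    windows = [config.effect_window]
    if config.post_effect:
        windows.append(config.post_effect_window)
    for window in windows:
        for i, label in enumerate(labels):
            base = p_neg if label == "negative" else p_pos
            jitter_db = rng.normal(0.0, config.trial_power_sd_db)
            power = base * 10.0 ** (jitter_db / 10.0)
            freq = rng.uniform(*effect_band)
            burst = oscillatory_burst(freq, np.sqrt(power), window, times,
                                      phase=rng.uniform(0.0, 2.0 * np.pi))
            data[i, eff_idx, :] += burst

    metadata = pd.DataFrame({
        "rating": labels,
        "previous_rating": np.concatenate([[NO_PREVIOUS], labels[:-1]]),
        "subject": subject_id,
        "experiment": experiment,
    })
    return EpochSet(data, times, config.sampling_rate, montage.channels, metadata)


def simulate_subject(config: SimConfig, subject_index: int) -> SubjectData:
    """Simulate one participant: both experiments plus a behavior record.

    Bit-identical under identical config + seed, independent of how many
    other subjects are generated.
    """
    montage = config.montage()
    b1, b2 = _subject_bias(config, subject_index)
    # subjects with a stronger negativity bias carry a stronger effect, so
    # the bias x power-difference correlation analysis has signal to find
    mean_bias = (config.bias_mean_exp1 + config.bias_mean_exp2) / 2.0
    coupling = config.effect_bias_coupling_db * ((b1 + b2) / 2.0 - mean_bias)
    effect_db = config.effect_size_db + coupling if config.effect_size_db != 0.0 else 0.0

    ch2 = config.effect_channels_exp2 or config.effect_channels
    band2 = config.effect_band_exp2 or config.effect_band

    exp1 = _simulate_epochs(config, montage, config.n_trials_exp1, b1,
                            effect_db, config.effect_channels,
                            config.effect_band, subject_index, 1,
                            _subject_rng(config.seed, subject_index, stream=1))
    exp2 = _simulate_epochs(config, montage, config.n_trials_exp2, b2,
                            effect_db, ch2, band2, subject_index, 2,
                            _subject_rng(config.seed, subject_index, stream=2))

    qrng = _subject_rng(config.seed, subject_index, stream=3)
    behavior = {
        "subject": subject_index,
        "bias_prob_exp1": b1,
        "bias_prob_exp2": b2,
        "effect_db": effect_db,
        "bdi2": float(np.clip(np.round(qrng.normal(4.1, 3.3)), 0, 63)),
        "stai_s": float(np.clip(np.round(qrng.normal(30.9, 5.6)), 20, 80)),
        "stai_t": float(np.clip(np.round(qrng.normal(31.0, 7.3)), 20, 80)),
    }
    return SubjectData(exp1, exp2, behavior)


def simulate_cohort(config: SimConfig) -> Iterator[SubjectData]:
    """Lazily yield the cohort's subjects (epochs are large; stream them)."""
    for i in range(config.n_subjects):
        yield simulate_subject(config, i)


# ---------------------------------------------------------------------------
# direct statistical-map simulation (for calibrating the cluster test)


def simulate_difference_maps(n_subjects: int, n_channels: int, n_freqs: int,
                             n_times: int, rng: np.random.Generator,
                             effect_block=None, effect_db: float = 0.0,
                             noise_sd: float = 1.0) -> np.ndarray:
    """Per-subject power-difference maps: i.i.d. Gaussian noise plus an
    optional constant dB offset inside a (channels, freqs, times) index
    block.  Used to calibrate/validate the cluster permutation test without
    simulating raw EEG.
    """
    maps = rng.normal(0.0, noise_sd, size=(n_subjects, n_channels, n_freqs, n_times))
    if effect_block is not None and effect_db != 0.0:
        ch, fr, ti = (np.asarray(ix, dtype=int) for ix in effect_block)
        maps[np.ix_(np.arange(n_subjects), ch, fr, ti)] += effect_db
    return maps
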