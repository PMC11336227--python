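"""Sliding Hann-taper time-frequency decomposition and dB baselining.

Power at (channel, frequency f, center time t) is the squared magnitude of
the Hann-tapered discrete Fourier coefficient at f of the 500 ms data
segment centered on t, stepped in 50 ms hops.  The taper-energy
normalization makes a unit-amplitude on-grid sinusoid yield power 1
regardless of window length.  Centers whose analysis window would overrun
the epoch are undefined (NaN), never zero-padded.

Baseline correction expresses power as 10*log10(power / mean baseline
power) per channel and frequency, with the baseline window recorded in the
result.  The decoding branch consumes raw (uncorrected) power.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .epochs import EpochSet

__all__ = [
    "TimeFreqRep",
    "sliding_hann_spectrogram",
    "db_baseline",
    "condition_average",
    "time_average",
    "band_power",
]


@dataclass
class TimeFreqRep:
    """Power over observations x channels x frequencies x times.

    ``power`` is in uV^2 (unit="raw") or dB relative to the recorded
    baseline window (unit="dB").  Undefined points (analysis window beyond
    the epoch) are NaN.  The observation axis holds trials for single-trial
    decompositions and has length 1 for condition averages.
    """

    power: np.ndarray = field(repr=False)
    freqs: np.ndarray
    times: np.ndarray
    channels: tuple
    unit: str = "raw"
    window_length: float = 500.0
    baseline: tuple | None = None
    trial_count: int | None = None

    def __post_init__(self):
        self.power = np.asarray(self.power, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.power.ndim != 4:
            raise ValueError("power must be obs x channels x freqs x times")
        n_obs, n_ch, n_f, n_t = self.power.shape
        if (len(self.channels), len(self.freqs), len(self.times)) != (n_ch, n_f, n_t):
            raise ValueError("axes do not match power array")
        if self.unit not in ("raw", "dB"):
            raise ValueError("unit must be 'raw' or 'dB'")
        if self.unit == "raw":
            defined = ~np.isnan(self.power)
            if np.any(self.power[defined] < 0):
                raise ValueError("raw power must be non-negative")
            if self.baseline is not None:
                raise ValueError("baseline window is only recorded for dB data")
        elif self.baseline is None:
            raise ValueError("dB data must record its baseline window")

    @property
    def n_obs(self) -> int:
        return self.power.shape[0]

    def defined_mask(self) -> np.ndarray:
        """Boolean (freqs x times broadcastable) mask of defined centers."""
        return ~np.isnan(self.power).any(axis=(0, 1, 2))

    def select_obs(self, indices) -> "TimeFreqRep":
        return replace(self, power=self.power[np.asarray(indices, dtype=int)])


def _hann(n: int) -> np.ndarray:
    # periodic Hann taper
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(n) / n))


def sliding_hann_spectrogram(epochs: EpochSet, freqs=None, times=None,
                             window_length: float = 500.0,
                             chunk_trials: int = 16) -> TimeFreqRep:
    """Single-trial sliding-window Hann-taper spectrogram.

    Parameters
    ----------
    freqs : Hz axis (default 2..120 step 1); every frequency must be below
        the Nyquist frequency.
    times : ms axis of window centers (default -2000..+2000 step 50);
        centers are snapped to the sample grid.
    window_length : analysis window in ms (default 500).
    """
    if freqs is None:
        freqs = np.arange(2.0, 121.0, 1.0)
    if times is None:
        times = np.arange(epochs.times[0], epochs.times[-1] + 1e-9, 50.0)
    freqs = np.asarray(freqs, dtype=float)
    times = np.asarray(times, dtype=float)
    nyquist = epochs.sfreq / 2.0
    if np.any(freqs >= nyquist):
        raise ValueError(f"frequencies must be below the Nyquist ({nyquist} Hz)")
    span = epochs.times[-1] - epochs.times[0]
    if window_length > span:
        raise ValueError("window_length exceeds the epoch span")

    sfreq = epochs.sfreq
    dt = 1000.0 / sfreq
    n_samples = epochs.data.shape[-1]
    L = int(round(window_length / 1000.0 * sfreq))
    half = L // 2
    center_idx = np.round((times - epochs.times[0]) / dt).astype(int)
    starts = center_idx - half
    defined = (starts >= 0) & (starts + L <= n_samples)

    w = _hann(L)
    norm = (w.sum() / 2.0) ** 2
    t_seg = np.arange(L) / sfreq
    phase = 2.0 * np.pi * freqs[:, None] * t_seg[None, :]
    k_cos = w[None, :] * np.cos(phase)  # (F, L)
    k_sin = w[None, :] * np.sin(phase)

    n_trials, n_channels = epochs.data.shape[:2]
    out = np.full((n_trials, n_channels, len(freqs), len(times)), np.nan)
    def_starts = starts[defined]
    if def_starts.size:
        gather = def_starts[:, None] + np.arange(L)[None, :]  # (K, L)
        for t0 in range(0, n_trials, chunk_trials):
            sl = slice(t0, min(t0 + chunk_trials, n_trials))
            segs = epochs.data[sl][:, :, gather]  # (T, C, K, L)
            re = np.einsum("tckl,fl->tcfk", segs, k_cos, optimize=True)
            im = np.einsum("tckl,fl->tcfk", segs, k_sin, optimize=True)
            out[sl][..., defined] = (re * re + im * im) / norm
    return TimeFreqRep(out, freqs, times, tuple(epochs.channels),
                       unit="raw", window_length=window_length)


def db_baseline(tfr: TimeFreqRep, baseline: tuple = (-1500.0, -500.0)) -> TimeFreqRep:
    """Decibel baseline correction: 10*log10(power / mean baseline power).

    The baseline mean is taken over window centers inside the closed
    ``baseline`` window, per observation, channel and frequency; the window
    must be fully defined in the decomposition.
    """
    if tfr.unit != "raw":
        raise ValueError("db_baseline expects raw power")
    in_base = (tfr.times >= baseline[0]) & (tfr.times <= baseline[1])
    if not in_base.any():
        raise ValueError("baseline window contains no time bins")
    base = tfr.power[..., in_base]
    if np.isnan(base).any():
        raise ValueError("baseline window contains undefined (edge) bins")
    mean = base.mean(axis=-1, keepdims=True)
    if np.any(mean == 0.0):
        raise ValueError("degenerate baseline: zero mean power")
    with np.errstate(divide="ignore"):
        db = 10.0 * np.log10(tfr.power / mean)
    return replace(tfr, power=db, unit="dB", baseline=tuple(baseline))


def condition_average(tfr: TimeFreqRep, selections: dict) -> dict:
    """Mean power over selected trials, one map per condition label.

    ``selections`` maps label -> TrialSelection (or index array); the
    selections must be non-empty and equally sized (use
    :func:`prestim.epochs.equalize_trials` first).
    """
    sizes = set()
    idx = {}
    for label, sel in selections.items():
        arr = np.asarray(getattr(sel, "indices", sel), dtype=int)
        if arr.size == 0:
            raise ValueError(f"empty selection for class {label!r}")
        idx[label] = arr
        sizes.add(arr.size)
    if len(sizes) > 1:
        raise ValueError("selections must be equalized to the same size")
    out = {}
    for label, arr in idx.items():
        mean = tfr.power[arr].mean(axis=0, keepdims=True)
        out[label] = replace(tfr, power=mean, trial_count=int(arr.size))
    return out


def time_average(tfr: TimeFreqRep, window: tuple = (-1000.0, -200.0),
                 fmax: float = 60.0) -> tuple:
    """Average power over time-bin centers in the closed ``window``.

    Returns ``(features, freqs)`` where features has shape (obs, channels,
    frequencies) restricted to 2..fmax Hz.  Used to build decoding features
    (on raw power) and to summarize windows.
    """
    in_win = (tfr.times >= window[0]) & (tfr.times <= window[1])
    f_sel = (tfr.freqs >= 2.0) & (tfr.freqs <= fmax)
    block = tfr.power[:, :, f_sel][..., in_win]
    defined = ~np.isnan(block).any(axis=(0, 1, 2))
    if not defined.any():
        raise ValueError("window contains no defined time bins")
    block = block[..., defined]
    return block.mean(axis=-1), tfr.freqs[f_sel]


def band_power(tfr: TimeFreqRep, channels, band: tuple, window: tuple) -> np.ndarray:
    """Per-observation mean raw power over a channel set, band and window."""
    ch_idx = [tfr.channels.index(c) for c in channels]
    f_sel = (tfr.freqs >= band[0]) & (tfr.freqs <= band[1])
    t_sel = (tfr.times >= window[0]) & (tfr.times <= window[1])
    block = tfr.power[:, ch_idx][:, :, f_sel][..., t_sel]
    return np.nanmean(block, axis=(1, 2, 3))
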