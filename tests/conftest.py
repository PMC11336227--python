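"""Shared fixtures and builders for the prestim test suite."""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from prestim.epochs import EpochSet
from prestim.montage import Montage, load_acticap60
from prestim.tfr import TimeFreqRep

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

SMALL_CHANNELS = ("CP3", "CP5", "C3", "C4", "P3", "P4", "O1", "O2")


@pytest.fixture(scope="session")
def full_montage() -> Montage:
    return load_acticap60()


@pytest.fixture(scope="session")
def small_montage(full_montage) -> Montage:
    return full_montage.subset(SMALL_CHANNELS)


@pytest.fixture(scope="session")
def chain_adjacency():
    """Simple 4-channel chain graph: 0-1-2-3."""
    adj = np.zeros((4, 4), dtype=bool)
    for i in range(3):
        adj[i, i + 1] = adj[i + 1, i] = True
    return adj


def make_epochs(n_trials=6, n_channels=3, sfreq=500.0, window=(-1000.0, 1000.0),
                ratings=None, data=None, seed=0) -> EpochSet:
    """Small EpochSet with noise data and cyclic ratings."""
    rng = np.random.default_rng(seed)
    dt = 1000.0 / sfreq
    times = np.arange(window[0], window[1] + dt / 2.0, dt)
    if data is None:
        data = rng.standard_normal((n_trials, n_channels, len(times)))
    if ratings is None:
        cycle = ("negative", "positive")
        ratings = [cycle[i % 2] for i in range(n_trials)]
    md = pd.DataFrame({
        "rating": list(ratings),
        "previous_rating": ["none"] + list(ratings[:-1]),
    })
    channels = tuple(f"ch{i}" for i in range(n_channels))
    return EpochSet(data, times, sfreq, channels, md)


def make_tfr(power, freqs=None, times=None, channels=None, unit="raw",
             window_length=500.0, baseline=None) -> TimeFreqRep:
    power = np.asarray(power, dtype=float)
    _, n_ch, n_f, n_t = power.shape
    if freqs is None:
        freqs = np.arange(2.0, 2.0 + n_f)
    if times is None:
        times = -1000.0 + 50.0 * np.arange(n_t)
    if channels is None:
        channels = tuple(f"ch{i}" for i in range(n_ch))
    return TimeFreqRep(power, freqs, times, channels, unit=unit,
                       window_length=window_length, baseline=baseline)


def write_brainvision(directory: Path, data_uv: np.ndarray, sfreq: float,
                      channels) -> Path:
    """Write a minimal synthetic BrainVision recording; returns the .vhdr path.

    ``data_uv`` is channels x samples in microvolts, stored as IEEE float32
    with a 0.1 uV resolution unit.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    n_ch = len(channels)
    interval_us = int(round(1e6 / sfreq))
    ch_lines = "\n".join(
        f"Ch{i + 1}={name},,0.1,µV" for i, name in enumerate(channels))
    (directory / "rec.vhdr").write_text(
        "Brain Vision Data Exchange Header File Version 1.0\n"
        "[Common Infos]\n"
        "DataFile=rec.eeg\nMarkerFile=rec.vmrk\nDataFormat=BINARY\n"
        f"DataOrientation=MULTIPLEXED\nNumberOfChannels={n_ch}\n"
        f"SamplingInterval={interval_us}\n"
        "[Binary Infos]\nBinaryFormat=IEEE_FLOAT_32\n"
        f"[Channel Infos]\n{ch_lines}\n")
    (directory / "rec.vmrk").write_text(
        "Brain Vision Data Exchange Marker File, Version 1.0\n"
        "[Common Infos]\nDataFile=rec.eeg\n"
        "[Marker Infos]\nMk1=New Segment,,1,1,0,0\n")
    # stored value = physical value / resolution
    (np.asarray(data_uv, dtype=np.float32) / np.float32(0.1)).T.ravel().tofile(
        directory / "rec.eeg")
    return directory / "rec.vhdr"
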