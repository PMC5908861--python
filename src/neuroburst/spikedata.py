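"""Spike-train containers, file I/O, spike extraction and a parametric
burst-pause generator.

The central container is :class:`SpikeTrainSet`: per-channel spike time
stamps (seconds, 0-based from epoch start) for one recording epoch.
Every downstream stage — burst detection, spectra, synchrony,
trajectories — consumes this one type, whether the spikes came from a
recording, from the parametric generator here, or from the GIF network
simulator in :mod:`neuroburst.gif`.

Spike tables are stored either as CSV with header ``channel,time_s`` or
as HDF5 with one float64 dataset per channel under ``/spikes/<channel>``
and the epoch length in the root attribute ``duration_s``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy import signal

logger = logging.getLogger(__name__)

__all__ = [
    "SpikeTrainSet",
    "RawTrace",
    "BurstPauseGenConfig",
    "read_spike_table",
    "write_spike_table",
    "bandpass",
    "detect_spikes",
    "generate_burst_pause",
]


@dataclass
class SpikeTrainSet:
    """Per-channel spike time stamps for one recording epoch.

    Parameters
    ----------
    channels : list
        Channel identifiers (ints or strings), one per train.
    spikes : dict
        Mapping channel id -> sorted float64 array of spike times in
        seconds, each within ``[0, duration]``.
    duration : float
        Epoch length in seconds.
    sampling_note : float, optional
        Original sampling rate in Hz when the trains were extracted from
        raw voltage traces; purely informational.
    """

    channels: list
    spikes: dict
    duration: float
    sampling_note: float | None = None

    def __post_init__(self) -> None:
        if self.duration < 0:
            raise ValueError("duration must be non-negative")
        clean = {}
        for ch in self.channels:
            t = np.asarray(self.spikes.get(ch, ()), dtype=float)
            if t.size and np.any(np.diff(t) < 0):
                warnings.warn(f"channel {ch}: spike times were unsorted; sorting")
                t = np.sort(t)
            if t.size and (t[0] < 0 or t[-1] > self.duration):
                raise ValueError(
                    f"channel {ch}: spike times outside [0, {self.duration}]"
                )
            clean[ch] = t
        self.spikes = clean

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def n_spikes(self, channel=None) -> int:
        if channel is not None:
            return int(self.spikes[channel].size)
        return int(sum(t.size for t in self.spikes.values()))

    def pooled(self) -> np.ndarray:
        """All spike times across channels, merged and sorted."""
        if not self.channels:
            return np.empty(0)
        return np.sort(np.concatenate([self.spikes[c] for c in self.channels]))

    def subset(self, channels) -> "SpikeTrainSet":
        return SpikeTrainSet(
            channels=list(channels),
            spikes={c: self.spikes[c] for c in channels},
            duration=self.duration,
            sampling_note=self.sampling_note,
        )


@dataclass
class RawTrace:
    """A raw extracellular voltage trace for one channel.

    ``samples`` are in microvolts, ``rate`` in Hz (MEA amplifiers in
    this preparation digitise at a nominal 25 kHz).
    """

    channel: object
    samples: np.ndarray
    rate: float = 25_000.0

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    return "hdf5" if path.suffix.lower() in {".h5", ".hdf5", ".hdf"} else "csv"


def read_spike_table(path, format: str | None = None, duration: float | None = None) -> SpikeTrainSet:
    """Read a spike table (CSV ``channel,time_s`` or HDF5) into a
    :class:`SpikeTrainSet`.

    ``duration`` overrides the stored epoch length; for CSV (which
    carries no metadata) the default is the last spike time.
    Malformed CSV rows raise with the offending line number; unsorted
    times are sorted with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        try:
            df = pd.read_csv(path, dtype={"channel": str})
        except pd.errors.EmptyDataError:
            return SpikeTrainSet(channels=[], spikes={}, duration=duration or 0.0)
        if df.empty:
            return SpikeTrainSet(channels=[], spikes={}, duration=duration or 0.0)
        if not {"channel", "time_s"}.issubset(df.columns):
            raise ValueError(f"{path}: expected columns 'channel,time_s'")
        times = pd.to_numeric(df["time_s"], errors="coerce")
        bad = np.nonzero(~np.isfinite(times.to_numpy()))[0]
        if bad.size:
            # +2: header line plus 1-based indexing
            raise ValueError(f"{path}: malformed time_s value at line {bad[0] + 2}")
        channels = list(dict.fromkeys(df["channel"]))
        # unsorted times are passed through: the SpikeTrainSet
        # constructor sorts them and emits the warning
        spikes = {ch: times[df["channel"] == ch].to_numpy() for ch in channels}
        dur = duration if duration is not None else float(times.max())
        return SpikeTrainSet(channels=channels, spikes=spikes, duration=dur)
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            dur = float(f.attrs.get("duration_s", 0.0))
            spikes = {}
            if "spikes" in f:
                for name in f["spikes"]:
                    spikes[name] = np.asarray(f["spikes"][name], dtype=float)
            channels = sorted(spikes)
        if duration is not None:
            dur = duration
        elif dur == 0.0 and spikes:
            dur = max((t[-1] for t in spikes.values() if t.size), default=0.0)
        return SpikeTrainSet(channels=channels, spikes=spikes, duration=dur)
    raise ValueError(f"unknown format {fmt!r} (use 'csv' or 'hdf5')")


def write_spike_table(sts: SpikeTrainSet, path, format: str | None = None) -> None:
    """Write a :class:`SpikeTrainSet` to CSV or HDF5 (see module docs
    for the layouts). Round-trips are lossless to float64 precision."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        rows = [
            (ch, t)
            for ch in sts.channels
            for t in sts.spikes[ch]
        ]
        pd.DataFrame(rows, columns=["channel", "time_s"]).to_csv(path, index=False)
    elif fmt == "hdf5":
        with h5py.File(path, "w") as f:
            f.attrs["duration_s"] = sts.duration
            grp = f.create_group("spikes")
            for ch in sts.channels:
                grp.create_dataset(str(ch), data=sts.spikes[ch], dtype="f8")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def bandpass(trace: RawTrace, low: float, high: float, order: int = 4) -> RawTrace:
    """Zero-phase Butterworth band-pass of a raw trace.

    Default use is the 200 Hz – 2 kHz band that isolates extracellular
    spikes from slow field fluctuations. Applied forward-backward
    (``sosfiltfilt``) so spike times are not shifted by filter delay.
    """
    nyq = trace.rate / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(f"band ({low}, {high}) invalid for rate {trace.rate}")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=trace.rate, output="sos")
    out = signal.sosfiltfilt(sos, trace.samples)
    return RawTrace(channel=trace.channel, samples=out, rate=trace.rate)


def detect_spikes(
    trace: RawTrace,
    threshold_sd: float = 7.0,
    dead_time: float = 1e-3,
) -> np.ndarray:
    """Threshold-based multiunit spike extraction from one channel.

    The noise SD is estimated robustly as ``median(|x|)/0.6745`` (the
    MAD estimator, insensitive to the spikes themselves) and events are
    detections where ``|x|`` crosses ``threshold_sd`` times that value.
    Within each crossing, the spike time is the local absolute extremum,
    and at most one spike is kept per ``dead_time`` window (default
    1 ms, i.e. the multiunit time-stamp resolution). This
    absolute-amplitude criterion approximates the peak-to-peak
    thresholding of commercial MEA acquisition software, whose exact
    operator is unpublished.

    Returns spike times in seconds. A constant-zero trace yields no
    detections (noise SD 0 is treated as "nothing to detect").
    """
    if threshold_sd <= 0:
        raise ValueError("threshold_sd must be positive")
    if dead_time < 0:
        raise ValueError("dead_time must be non-negative")
    x = trace.samples
    noise_sd = np.median(np.abs(x)) / 0.6745
    if noise_sd == 0:
        return np.empty(0)
    thr = threshold_sd * noise_sd
    above = np.abs(x) > thr
    if not above.any():
        return np.empty(0)
    dead = max(1, int(round(dead_time * trace.rate)))
    idx = np.nonzero(above)[0]
    # split threshold crossings into events separated by >= dead samples
    breaks = np.nonzero(np.diff(idx) >= dead)[0]
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    peaks = []
    last = -np.inf
    for s, e in zip(starts, ends):
        seg = idx[s : e + 1]
        p = seg[np.argmax(np.abs(x[seg]))]
        if p - last >= dead:
            peaks.append(p)
            last = p
    return np.asarray(peaks, dtype=float) / trace.rate


@dataclass
class BurstPauseGenConfig:
    """Parameters of the parametric (renewal-process) burst-pause
    generator.

    Defaults emulate a mature 60-channel culture: dish-wide bursts at
    0.3 Hz, ~0.3 s long, recruiting 80% of channels firing at 50 Hz
    inside the burst over a 2 Hz background, with 10 ms per-channel
    onset jitter.
    """

    n_channels: int = 60
    duration: float = 300.0
    burst_rate: float = 0.3
    burst_len: float = 0.3
    within_burst_rate: float = 50.0
    background_rate: float = 2.0
    participation: float = 0.8
    jitter_sd: float = 0.01
    regularity: float = 4.0
    seed: int | None = None
    _realized_onsets: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        for name in ("burst_rate", "burst_len", "within_burst_rate", "background_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.participation <= 1:
            raise ValueError("participation must be in [0, 1]")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if self.regularity <= 0:
            raise ValueError("regularity must be positive")


def generate_burst_pause(config: BurstPauseGenConfig) -> SpikeTrainSet:
    """Generate synthetic dish-wide burst-pause activity.

    Burst onsets follow a renewal process at ``burst_rate``: successive
    inter-onset gaps are gamma-distributed with mean ``1/burst_rate``
    and shape ``regularity`` (shape 1 is a Poisson process; the default
    shape 4 reproduces the quasi-regular pacing that adaptation imposes
    on cultured networks and keeps bursts from overlapping at realistic
    rates). Each burst recruits
    ``ceil(participation * n_channels)`` randomly
    chosen channels which fire Poisson at ``within_burst_rate`` for
    ``burst_len`` seconds, with per-channel onset jitter
    ``N(0, jitter_sd^2)``. Independent Poisson background firing at
    ``background_rate`` is added on every channel. Deterministic under
    a fixed ``config.seed``.

    The realized burst onset times are stored on
    ``config._realized_onsets`` for bookkeeping in parameter-recovery
    tests.
    """
    rng = np.random.default_rng(config.seed)
    n_ch = config.n_channels
    dur = config.duration
    channels = list(range(n_ch))

    if config.burst_rate > 0:
        # gamma-renewal onset sequence covering [0, duration]
        mean_gap = 1.0 / config.burst_rate
        n_max = int(np.ceil(config.burst_rate * dur + 6 * np.sqrt(config.burst_rate * dur / config.regularity) + 8))
        gaps = rng.gamma(config.regularity, mean_gap / config.regularity, size=n_max)
        onsets = np.cumsum(gaps) - rng.uniform(0.0, mean_gap)  # random phase
        while onsets.size and onsets[-1] < dur:  # rare: extend the tail
            extra = rng.gamma(config.regularity, mean_gap / config.regularity, size=8)
            onsets = np.concatenate([onsets, onsets[-1] + np.cumsum(extra)])
        onsets = onsets[(onsets >= 0) & (onsets <= dur)]
    else:
        onsets = np.empty(0)
    config._realized_onsets = onsets

    recruit_n = int(np.ceil(config.participation * n_ch))
    per_ch: list[list[np.ndarray]] = [[] for _ in range(n_ch)]

    for onset in onsets:
        members = rng.choice(n_ch, size=recruit_n, replace=False)
        jit = rng.normal(0.0, config.jitter_sd, size=recruit_n)
        counts = rng.poisson(config.within_burst_rate * config.burst_len, size=recruit_n)
        for ch, j, k in zip(members, jit, counts):
            t = onset + j + rng.uniform(0.0, config.burst_len, size=k)
            per_ch[ch].append(t)

    for ch in range(n_ch):
        k = rng.poisson(config.background_rate * dur)
        per_ch[ch].append(rng.uniform(0.0, dur, size=k))

    spikes = {}
    for ch in range(n_ch):
        t = np.concatenate(per_ch[ch]) if per_ch[ch] else np.empty(0)
        t = np.sort(t[(t >= 0) & (t <= dur)])
        spikes[ch] = t
    return SpikeTrainSet(channels=channels, spikes=spikes, duration=dur)
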