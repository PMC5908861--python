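"""Spike-density functions and synchronized-burst detection.

The population activity of a bursting culture is summarised by two
regularly sampled signals:

* the per-channel spike density function (SDF): the spike train
  convolved with a unit-area Gaussian kernel (SD 100 ms by default),
  evaluated on a 1 kHz grid, and the population mean SDF (mSDF);
* the dish-wide window-count histogram: the pooled spike count in a
  100 ms window slid along time in 1 ms steps.

Synchronized bursts — the in vitro analogue of the cortical UP state —
are spans where the window count exceeds a fixed threshold (40 spikes
per window by default). Each burst is then characterised on the mSDF
envelope: its duration (BD) is the width at 25% of the envelope
maximum, the inter-burst interval (IBI) is the peak-to-peak distance of
consecutive bursts, and the initial/final slopes are the extrema of the
first derivative of the max-normalized envelope on the rising/decaying
phase.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .spikedata import SpikeTrainSet

logger = logging.getLogger(__name__)

__all__ = [
    "DensityTrace",
    "Burst",
    "BurstCatalog",
    "sdf",
    "msdf",
    "window_count_histogram",
    "detect_bursts",
    "burst_slopes",
    "bd_spikecount_relation",
]


@dataclass
class DensityTrace:
    """A regularly sampled firing-rate signal.

    ``values`` are non-negative (Hz for SDF/mSDF, spikes/window for the
    window-count histogram), sampled at ``rate`` Hz starting at ``t0``
    seconds. ``kind`` is one of ``{"sdf", "msdf", "window_count"}``.
    """

    values: np.ndarray
    rate: float = 1000.0
    t0: float = 0.0
    kind: str = "sdf"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.rate

    @property
    def duration(self) -> float:
        return self.values.size / self.rate


@dataclass
class Burst:
    """One detected synchronized burst.

    ``onset_t``/``offset_t`` are the 25%-of-maximum boundary crossings
    of the mSDF envelope, ``peak_t`` the window-count maximum inside the
    supra-threshold span, ``BD = offset_t - onset_t``. ``n_spikes``
    counts pooled spikes over all channels within the boundaries.
    Slopes are on the max-normalized envelope (units 1/s); ``final_slope``
    is reported as a magnitude. ``edge_truncated`` flags bursts whose
    25% boundary ran into the epoch edge; such bursts are excluded from
    BD and slope statistics.
    """

    onset_t: float
    peak_t: float
    offset_t: float
    peak_value: float
    n_spikes: int
    initial_slope: float | None = None
    final_slope: float | None = None
    edge_truncated: bool = False

    @property
    def BD(self) -> float:
        return self.offset_t - self.onset_t


@dataclass
class BurstCatalog:
    """Ordered list of detected bursts plus the IBI sequence
    (peak-to-peak intervals of consecutive bursts)."""

    bursts: list
    duration: float
    metadata: dict = field(default_factory=dict)

    @property
    def n_bursts(self) -> int:
        return len(self.bursts)

    @property
    def ibis(self) -> np.ndarray:
        peaks = np.array([b.peak_t for b in self.bursts])
        return np.diff(peaks)

    @property
    def burst_rate(self) -> float:
        """Detected bursts per second of epoch."""
        return self.n_bursts / self.duration if self.duration > 0 else 0.0

    def valid(self) -> list:
        """Bursts usable for BD/slope statistics (not edge-truncated)."""
        return [b for b in self.bursts if not b.edge_truncated]

    def summary(self) -> dict:
        v = self.valid()
        bds = np.array([b.BD for b in v])
        iss = np.array([b.initial_slope for b in v if b.initial_slope is not None])
        fss = np.array([b.final_slope for b in v if b.final_slope is not None])
        nsp = np.array([b.n_spikes for b in v])
        ibis = self.ibis
        return {
            "n_bursts": self.n_bursts,
            "burst_rate_hz": self.burst_rate,
            "mean_bd_s": float(bds.mean()) if bds.size else np.nan,
            "mean_ibi_s": float(ibis.mean()) if ibis.size else np.nan,
            "mean_initial_slope": float(iss.mean()) if iss.size else np.nan,
            "mean_final_slope": float(fss.mean()) if fss.size else np.nan,
            "mean_spikes_per_burst": float(nsp.mean()) if nsp.size else np.nan,
        }


def _grid_length(duration: float, rate: float) -> int:
    return int(np.ceil(duration * rate))


def _bin_spikes(times: np.ndarray, duration: float, rate: float) -> np.ndarray:
    n = _grid_length(duration, rate)
    if n == 0:
        return np.zeros(0)
    idx = np.minimum((np.asarray(times) * rate).astype(np.int64), n - 1)
    return np.bincount(idx, minlength=n).astype(float)


def sdf(
    spike_times: np.ndarray,
    duration: float,
    sigma: float = 0.1,
    rate: float = 1000.0,
) -> DensityTrace:
    """Spike density function of one channel.

    Sum over spikes of unit-area Gaussians (SD ``sigma``, default
    100 ms) centred at the spike times, evaluated on a regular grid at
    ``rate`` Hz. The trapezoidal integral of the trace approximates the
    spike count (up to edge truncation).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    counts = _bin_spikes(np.asarray(spike_times, dtype=float), duration, rate)
    if counts.size == 0:
        return DensityTrace(values=counts, rate=rate, kind="sdf")
    # Gaussian filter of the count sequence; multiplying by the grid rate
    # turns counts/bin into a density in Hz with unit area per spike.
    vals = ndimage.gaussian_filter1d(
        counts, sigma=sigma * rate, mode="constant", truncate=6.0
    ) * rate
    return DensityTrace(values=vals, rate=rate, kind="sdf")


def msdf(
    sts: SpikeTrainSet,
    sigma: float = 0.1,
    rate: float = 1000.0,
) -> DensityTrace:
    """Population mean SDF: pointwise average of per-channel SDFs."""
    if sts.n_channels == 0:
        raise ValueError("mSDF requires at least one channel")
    # Mean of per-channel SDFs = SDF of the pooled train / n_channels
    # (linearity of the Gaussian convolution).
    pooled = sdf(sts.pooled(), sts.duration, sigma=sigma, rate=rate)
    return DensityTrace(
        values=pooled.values / sts.n_channels, rate=rate, kind="msdf"
    )


def window_count_histogram(
    sts: SpikeTrainSet,
    window: float = 0.1,
    rate: float = 1000.0,
) -> DensityTrace:
    """Dish-wide sliding window count: pooled spikes over all electrodes
    inside a ``window``-long box slid along time at the grid step
    (1 ms by default). ``values[k]`` is the count in
    ``[k/rate, k/rate + window)``.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    counts = _bin_spikes(sts.pooled(), sts.duration, rate)
    w = max(1, int(round(window * rate)))
    if counts.size == 0:
        return DensityTrace(values=counts, rate=rate, kind="window_count")
    # forward-looking boxcar sum: counts[k] + ... + counts[k+w-1]
    cs = np.concatenate(([0.0], np.cumsum(counts)))
    out = cs[w:] - cs[:-w]
    out = np.concatenate((out, cs[-1] - cs[-w:-1] if w > 1 else np.empty(0)))
    return DensityTrace(values=out, rate=rate, kind="window_count")


def _supra_spans(hist: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    """Contiguous index spans where hist > threshold (strict), as
    [start, end] inclusive."""
    above = hist > threshold
    if not above.any():
        return []
    d = np.diff(above.astype(np.int8))
    starts = list(np.nonzero(d == 1)[0] + 1)
    ends = list(np.nonzero(d == -1)[0])
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(above.size - 1)
    return list(zip(starts, ends))


def detect_bursts(
    sts: SpikeTrainSet,
    window: float = 0.1,
    threshold: float = 40.0,
    sigma: float = 0.1,
    rate: float = 1000.0,
    boundary_frac: float = 0.25,
) -> BurstCatalog:
    """Detect synchronized bursts in a spike-train set.

    Detection runs on the dish-wide sliding window count
    (:func:`window_count_histogram`): spans where the count strictly
    exceeds ``threshold`` spikes/window are candidate bursts; spans
    separated by less than one window length are merged so a single
    network event does not fragment on threshold jitter. The peak time
    of each burst is the window-count maximum within its span (window
    centre convention: span index + window/2). Burst boundaries are then
    found on the mSDF envelope by walking outward from the envelope
    maximum to the first crossing below ``boundary_frac`` (25%) of that
    maximum, bounded by the midpoint to the neighbouring burst; bursts
    whose boundary search runs into the epoch edge are flagged
    ``edge_truncated``. Initial/final slopes per burst come from
    :func:`burst_slopes` on the same envelope.
    """
    cat = BurstCatalog(
        bursts=[],
        duration=sts.duration,
        metadata={
            "window_s": window,
            "threshold": threshold,
            "sigma_s": sigma,
            "rate_hz": rate,
            "boundary_frac": boundary_frac,
        },
    )
    if sts.n_channels == 0 or sts.n_spikes() == 0:
        return cat
    hist = window_count_histogram(sts, window=window, rate=rate)
    spans = _supra_spans(hist.values, threshold)
    if not spans:
        return cat
    # merge spans separated by < one window length
    w_bins = max(1, int(round(window * rate)))
    merged = [list(spans[0])]
    for s, e in spans[1:]:
        if s - merged[-1][1] < w_bins:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    env = msdf(sts, sigma=sigma, rate=rate)
    ev = env.values
    n = ev.size
    half_w = 0.5 * window

    # window-count peak index per span (ties -> earliest)
    peak_idx = [s + int(np.argmax(hist.values[s : e + 1])) for s, e in merged]
    # envelope peak index per span, used for boundary walk
    env_peak_idx = [s + int(np.argmax(ev[s : min(e + w_bins, n - 1) + 1])) for s, e in merged]

    pooled = sts.pooled()
    bursts = []
    for k, (span, p_idx, ep_idx) in enumerate(zip(merged, peak_idx, env_peak_idx)):
        peak_t = p_idx / rate + half_w
        env_peak = ev[ep_idx]
        if env_peak <= 0:
            continue
        level = boundary_frac * env_peak
        lo_bound = 0 if k == 0 else (env_peak_idx[k - 1] + ep_idx) // 2
        hi_bound = n - 1 if k == len(merged) - 1 else (ep_idx + env_peak_idx[k + 1]) // 2
        i = ep_idx
        while i > lo_bound and ev[i] >= level:
            i -= 1
        onset_trunc = ev[i] >= level and i == lo_bound and k == 0 and lo_bound == 0
        j = ep_idx
        while j < hi_bound and ev[j] >= level:
            j += 1
        offset_trunc = ev[j] >= level and j == hi_bound and k == len(merged) - 1 and hi_bound == n - 1
        onset_t = i / rate
        offset_t = j / rate
        n_spk = int(np.count_nonzero((pooled >= onset_t) & (pooled <= offset_t)))
        b = Burst(
            onset_t=onset_t,
            peak_t=peak_t,
            offset_t=offset_t,
            peak_value=float(hist.values[p_idx]),
            n_spikes=n_spk,
            edge_truncated=bool(onset_trunc or offset_trunc),
        )
        if not b.edge_truncated:
            try:
                b.initial_slope, b.final_slope = burst_slopes(env, b)
            except ValueError:
                b.initial_slope = b.final_slope = None
        bursts.append(b)
    cat.bursts = bursts
    return cat


def burst_slopes(envelope: DensityTrace, burst: Burst) -> tuple[float, float]:
    """Initial and final slopes of one burst on its envelope.

    The envelope segment ``[onset_t, offset_t]`` is divided by its
    maximum (so slopes are invariant to amplitude scaling) and
    differentiated by central differences on the grid. The initial slope
    is the maximum derivative on the ascending phase (onset -> peak of
    the segment); the final slope is the magnitude of the minimum
    derivative on the descending phase. Units: 1/s.
    """
    rate = envelope.rate
    i0 = int(round((burst.onset_t - envelope.t0) * rate))
    i1 = int(round((burst.offset_t - envelope.t0) * rate))
    seg = envelope.values[i0 : i1 + 1]
    if seg.size < 3 or seg.max() <= 0:
        raise ValueError("burst segment too short or empty for slope estimation")
    norm = seg / seg.max()
    p = int(np.argmax(norm))
    if p == 0 or p == norm.size - 1:
        raise ValueError("degenerate burst: envelope peak at segment boundary")
    deriv = np.gradient(norm, 1.0 / rate)
    initial = float(np.max(deriv[: p + 1]))
    final = float(-np.min(deriv[p:]))
    if initial <= 0 or final <= 0:
        raise ValueError("non-positive slope: envelope not unimodal over burst")
    return initial, final


def bd_spikecount_relation(catalog: BurstCatalog, bins: int = 20):
    """Log-log relation between burst duration and spikes per burst.

    Least-squares line of ``log10(n_spikes)`` on ``log10(BD)``, the
    Pearson correlation of the log pairs, and marginal histograms of BD
    and spike count (log-spaced bins). Requires >= 3 non-degenerate
    bursts and non-constant BD.
    """
    v = [b for b in catalog.valid() if b.BD > 0 and b.n_spikes > 0]
    if len(v) < 3:
        raise ValueError("need at least 3 bursts for the BD/spike-count relation")
    bd = np.array([b.BD for b in v])
    ns = np.array([b.n_spikes for b in v], dtype=float)
    lx, ly = np.log10(bd), np.log10(ns)
    if np.allclose(lx, lx[0]):
        raise ValueError("burst durations are constant: regression undefined")
    res = stats.linregress(lx, ly)
    bd_hist = np.histogram(bd, bins=np.geomspace(bd.min(), bd.max() * (1 + 1e-12), bins + 1))
    ns_hist = np.histogram(ns, bins=np.geomspace(ns.min(), ns.max() * (1 + 1e-12), bins + 1))
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "correlation": float(res.rvalue),
        "bd_hist": bd_hist,
        "n_spikes_hist": ns_hist,
    }
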