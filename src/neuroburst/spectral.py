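"""FFT power spectrum of the population firing rate.

The slow oscillation of a bursting culture shows up as a dominant peak
at or below 1 Hz in the power spectrum of the mSDF, and sleep-like
recovery as an increase in power below 1.75 Hz. The mSDF (Gaussian
kernel SD 100 ms, 1 kHz grid) is mean-subtracted (DC removal) and
transformed with a one-sided FFT; frequency resolution is
``rate / n_samples``, i.e. ~3.3 mHz for a 300 s epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .burst import DensityTrace

__all__ = ["PowerSpectrum", "power_spectrum", "dominant_frequency", "band_power", "relative_power"]


@dataclass
class PowerSpectrum:
    """One-sided power spectrum: ``power[k]`` at ``freqs[k]`` (Hz),
    DC bin excluded after mean subtraction."""

    freqs: np.ndarray
    power: np.ndarray
    resolution: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.size != self.power.size:
            raise ValueError("freqs and power must have equal length")


def power_spectrum(trace: DensityTrace, window: str | None = None) -> PowerSpectrum:
    """One-sided FFT power spectrum of a density trace.

    The mean is subtracted first (DC removal), so the spectrum is
    invariant to adding a constant to the trace, and the zero-frequency
    bin is dropped. ``window="hann"`` applies a Hann taper before the
    transform (off by default). Power is ``|X_k|^2 / n``, which makes
    ``sum(power)`` equal to ``n * var`` up to one-sided folding
    (Parseval).
    """
    x = trace.values
    if x.size < 2 * trace.rate:
        raise ValueError("need at least 2 s of samples for a spectrum")
    x = x - x.mean()
    if window == "hann":
        x = x * np.hanning(x.size)
    elif window is not None:
        raise ValueError(f"unknown window {window!r}")
    n = x.size
    X = np.fft.rfft(x)
    power = (np.abs(X) ** 2) / n
    # one-sided: double everything except DC (and Nyquist for even n)
    power[1:] *= 2.0
    if n % 2 == 0:
        power[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / trace.rate)
    return PowerSpectrum(
        freqs=freqs[1:],
        power=power[1:],
        resolution=trace.rate / n,
        metadata={"n_samples": n, "rate_hz": trace.rate, "window": window},
    )


def dominant_frequency(spec: PowerSpectrum, band: tuple[float, float] | None = None) -> float:
    """Frequency of the maximal power bin, optionally restricted to a
    band ``(lo, hi]``; ties break toward the lower frequency. The slow
    oscillation band of interest is <= 1 Hz."""
    if band is None:
        mask = np.ones(spec.freqs.size, dtype=bool)
    else:
        lo, hi = band
        mask = (spec.freqs > lo) & (spec.freqs <= hi)
    if not mask.any():
        raise ValueError("band contains no spectral bins")
    f = spec.freqs[mask]
    p = spec.power[mask]
    return float(f[np.argmax(p)])  # argmax returns first index on ties


def band_power(spec: PowerSpectrum, lo: float, hi: float) -> float:
    """Total power in ``[lo, hi)`` (sum over bins, rectangle rule).
    The homeostasis readout band is (0, 1.75) Hz."""
    if not 0 <= lo < hi:
        raise ValueError("need 0 <= lo < hi")
    if lo > spec.freqs[-1]:
        raise ValueError("band lies outside the spectrum")
    mask = (spec.freqs >= lo) & (spec.freqs < hi)
    return float(spec.power[mask].sum())


def relative_power(recovery: PowerSpectrum, baseline: PowerSpectrum) -> PowerSpectrum:
    """Per-bin power ratio recovery/baseline; both spectra must share
    the same frequency grid (same epoch length and rate)."""
    if recovery.freqs.size != baseline.freqs.size or not np.allclose(
        recovery.freqs, baseline.freqs
    ):
        raise ValueError("spectra must share an identical frequency grid")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = recovery.power / baseline.power
    return PowerSpectrum(
        freqs=recovery.freqs.copy(),
        power=ratio,
        resolution=recovery.resolution,
        metadata={"kind": "relative_power"},
    )
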