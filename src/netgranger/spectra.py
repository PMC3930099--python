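"""Band-pass filtering and band-limited power spectral density summaries.

Network time courses sampled every 2 s (Nyquist 0.25 Hz) are restricted to
the 0.05-0.15 Hz band in which endogenous BOLD oscillations are maximal and
physiological noise minimal.  Filtering is zero-phase frequency-domain
masking (flat in-band response, cosine roll-off), so no phase distortion is
introduced that could corrupt lag-based causality estimates.  PSD summaries
use a Welch averaged periodogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "BandDefinition",
    "PSDSpectrum",
    "bandpass_filter",
    "welch_psd",
    "mean_band_psd",
]


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band in Hz; must lie strictly inside (0, Nyquist)."""

    low: float = 0.05
    high: float = 0.15

    def validate(self, sampling_interval: float) -> None:
        nyquist = 0.5 / sampling_interval
        if not (0.0 < self.low < self.high < nyquist):
            raise ValueError(
                f"band ({self.low}, {self.high}) Hz must satisfy "
                f"0 < low < high < Nyquist ({nyquist} Hz)"
            )


@dataclass(frozen=True)
class PSDSpectrum:
    """One-sided power spectral density estimate."""

    frequencies: np.ndarray  # Hz, strictly increasing
    density: np.ndarray  # power per Hz, >= 0
    method: str = "welch"

    def band_mean(self, band: BandDefinition) -> float:
        """Mean density over grid points within [low, high]."""
        in_band = (self.frequencies >= band.low) & (self.frequencies <= band.high)
        if not np.any(in_band):
            raise ValueError("no PSD grid points fall inside the band (series too short)")
        return float(np.mean(self.density[in_band]))


def bandpass_filter(
    timecourse: np.ndarray,
    band: BandDefinition = BandDefinition(),
    sampling_interval: float = 2.0,
    rolloff: float = 0.01,
) -> np.ndarray:
    """Zero-phase band-pass of a single-channel series.

    The rFFT of the mean-removed series is multiplied by a mask that is 1
    inside [low, high], falls as a raised cosine over ``rolloff`` Hz outside
    each edge, and is 0 beyond; the DC bin is always zeroed.  In-band power
    is preserved exactly; out-of-band power beyond the roll-off is removed.
    """
    x = np.asarray(timecourse, dtype=float)
    if x.ndim != 1:
        raise ValueError("bandpass_filter expects a single-channel 1-D series")
    if x.size < 32:
        raise ValueError("series too short to filter (need >= 32 samples)")
    band.validate(sampling_interval)
    freqs = np.fft.rfftfreq(x.size, d=sampling_interval)
    mask = np.zeros_like(freqs)
    inside = (freqs >= band.low) & (freqs <= band.high)
    mask[inside] = 1.0
    if rolloff > 0:
        lo_ramp = (freqs > band.low - rolloff) & (freqs < band.low)
        mask[lo_ramp] = 0.5 * (1 + np.cos(np.pi * (band.low - freqs[lo_ramp]) / rolloff))
        hi_ramp = (freqs > band.high) & (freqs < band.high + rolloff)
        mask[hi_ramp] = 0.5 * (1 + np.cos(np.pi * (freqs[hi_ramp] - band.high) / rolloff))
    mask[0] = 0.0
    spectrum = np.fft.rfft(x - x.mean())
    return np.fft.irfft(spectrum * mask, n=x.size)


def welch_psd(
    timecourse: np.ndarray,
    sampling_interval: float = 2.0,
    segment_length: int = 64,
) -> PSDSpectrum:
    """Welch averaged-periodogram PSD (Hann taper, 50% overlap)."""
    x = np.asarray(timecourse, dtype=float)
    if x.size < 32:
        raise ValueError("series too short for PSD estimation (need >= 32 samples)")
    nperseg = min(segment_length, x.size)
    f, pxx = signal.welch(
        x,
        fs=1.0 / sampling_interval,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend="constant",
        scaling="density",
    )
    return PSDSpectrum(frequencies=f, density=pxx, method="welch")


def mean_band_psd(
    timecourse: np.ndarray,
    band: BandDefinition = BandDefinition(),
    sampling_interval: float = 2.0,
    segment_length: int = 64,
) -> float:
    """Mean PSD (signal units^2 / Hz) over the grid points inside the band."""
    band.validate(sampling_interval)
    return welch_psd(timecourse, sampling_interval, segment_length).band_mean(band)
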