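"""Spectral indicators of regional activity: ALFF and fALFF.

The single-sided amplitude spectrum here is scaled so that the sum of squared
amplitudes equals the signal variance (Parseval). ALFF is the sum of
amplitudes over the frequency band (closed interval); fALFF divides that by
the amplitude sum over all non-DC bins up to Nyquist, giving a scale-free
value in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import detrend as _linear_detrend

__all__ = [
    "Band",
    "IndicatorError",
    "amplitude_spectrum",
    "compute_alff",
    "compute_falff",
    "falff_columns",
    "alff_columns",
]

_MIN_LEN = 8


class IndicatorError(ValueError):
    """Raised when an indicator is undefined for the given signal."""


@dataclass(frozen=True)
class Band:
    """Closed frequency interval in Hz."""

    low: float = 0.01
    high: float = 0.08

    def validate(self, sampling_interval: float) -> None:
        nyq = 0.5 / sampling_interval
        if not (0 < self.low < self.high):
            raise IndicatorError(f"need 0 < low < high, got [{self.low}, {self.high}]")
        if self.high >= nyq:
            raise IndicatorError(
                f"band high {self.high} Hz >= Nyquist {nyq} Hz"
            )


def _as_band(band) -> Band:
    if isinstance(band, Band):
        return band
    low, high = band
    return Band(float(low), float(high))


def _prepare(signal: np.ndarray, detrend: bool) -> np.ndarray:
    x = np.asarray(signal, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected signals as (time, series)")
    if x.shape[0] < _MIN_LEN:
        raise IndicatorError(f"signal too short ({x.shape[0]} < {_MIN_LEN} samples)")
    if not np.all(np.isfinite(x)):
        raise IndicatorError("signal contains non-finite values")
    if detrend:
        x = _linear_detrend(x, axis=0)
    return x - x.mean(axis=0)


def _spectrum_columns(x: np.ndarray, sampling_interval: float):
    """Variance-normalized single-sided amplitudes per column, DC excluded."""
    n = x.shape[0]
    X = np.fft.rfft(x, axis=0)
    amps = np.abs(X) / n
    amps[1:] *= np.sqrt(2.0)
    if n % 2 == 0:
        amps[-1] /= np.sqrt(2.0)  # Nyquist bin is unpaired
    freqs = np.fft.rfftfreq(n, d=sampling_interval)
    return freqs[1:], amps[1:]


def amplitude_spectrum(signal, sampling_interval: float, detrend: bool = False):
    """Single-sided amplitude spectrum of the demeaned signal.

    Returns ``(frequencies, amplitudes)`` excluding the DC bin, with
    ``sum(amplitudes**2) == var(signal)`` (Parseval consistency).
    """
    if sampling_interval <= 0:
        raise ValueError("sampling_interval must be positive")
    x = _prepare(np.asarray(signal, dtype=float).reshape(-1, 1), detrend)
    freqs, amps = _spectrum_columns(x, sampling_interval)
    return freqs, amps[:, 0]


def _band_mask(freqs: np.ndarray, band: Band) -> np.ndarray:
    # closed interval with a tiny tolerance for grid-point round-off
    eps = 1e-12
    return (freqs >= band.low - eps) & (freqs <= band.high + eps)


def compute_alff(signal, TR: float, band=Band(), detrend: bool = False) -> float:
    """Sum of in-band amplitude-spectrum values (amplitude units of the signal)."""
    band = _as_band(band)
    band.validate(TR)
    freqs, amps = amplitude_spectrum(signal, TR, detrend=detrend)
    return float(amps[_band_mask(freqs, band)].sum())


def compute_falff(signal, TR: float, band=Band(), detrend: bool = False) -> float:
    """In-band amplitude sum over the total non-DC amplitude sum, in [0, 1]."""
    band = _as_band(band)
    band.validate(TR)
    freqs, amps = amplitude_spectrum(signal, TR, detrend=detrend)
    total = amps.sum()
    if total <= 0:
        raise IndicatorError("fALFF undefined: signal has zero total amplitude")
    return float(amps[_band_mask(freqs, band)].sum() / total)


def alff_columns(signals, TR: float, band=Band(), detrend: bool = False) -> np.ndarray:
    """Vectorized ALFF over the columns of a (time, regions) matrix."""
    band = _as_band(band)
    band.validate(TR)
    x = _prepare(signals, detrend)
    freqs, amps = _spectrum_columns(x, TR)
    return amps[_band_mask(freqs, band)].sum(axis=0)


def falff_columns(signals, TR: float, band=Band(), detrend: bool = False) -> np.ndarray:
    """Vectorized fALFF over the columns of a (time, regions) matrix."""
    band = _as_band(band)
    band.validate(TR)
    x = _prepare(signals, detrend)
    freqs, amps = _spectrum_columns(x, TR)
    total = amps.sum(axis=0)
    if np.any(total <= 0):
        bad = int(np.argmax(total <= 0))
        raise IndicatorError(f"fALFF undefined for constant column {bad}")
    return amps[_band_mask(freqs, band)].sum(axis=0) / total
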