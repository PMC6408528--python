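"""Waveform and spectrum analytics for detector traces.

The spectral conventions are fixed package-wide so that amplitude
comparisons (pulse-width sweeps, marker-depth calibrations) are internally
consistent: magnitude of the FFT after a Tukey(0.1) window, ≥4× zero
padding, amplitude scaled by the sample interval (so the value
approximates the continuous Fourier magnitude, mPa·s per proton).
Absolute spectral units are internal — the physical contract is ratios and
slopes of amplitudes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import rfft, rfftfreq
from scipy.signal.windows import tukey

from .trace import PressureTrace

__all__ = [
    "Spectrum",
    "ResonancePeak",
    "BipolarMetrics",
    "spectrum",
    "resonance_amplitude",
    "bipolar_metrics",
    "trace_difference",
]

_TUKEY_ALPHA = 0.1
_PAD_FACTOR = 4
#: Sideband used to estimate the noise floor, Hz (above the n=1 marker
#: line of a 2 mm sphere, below n=2 harmonics only for short pulses).
_NOISE_BAND = (2.5e6, 4.0e6)
_NOISE_FLOOR_FACTOR = 5.0


@dataclass
class Spectrum:
    """One-sided magnitude spectra, one row per detector.

    ``amplitude`` is |FFT| × dt (mPa·s per proton); ``window`` and
    ``pad_factor`` record the fixed analysis settings.
    """

    freqs: np.ndarray
    amplitude: np.ndarray
    window: str = f"tukey({_TUKEY_ALPHA})"
    pad_factor: int = _PAD_FACTOR

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


def spectrum(
    trace: PressureTrace,
    t_start: float | None = None,
    pad_factor: int = _PAD_FACTOR,
) -> Spectrum:
    """Magnitude spectrum of each detector trace.

    ``t_start`` crops the trace (e.g. to the post-arrival segment of a
    ringdown) before windowing.  Requires uniform sampling — the trace
    container already enforces it.
    """
    times = trace.times
    p = trace.pressure
    if t_start is not None:
        keep = times >= t_start
        times = times[keep]
        p = p[:, keep]
    n = p.shape[1]
    if n < 8:
        raise ValueError("trace too short for spectral analysis")
    dt = float(times[1] - times[0])
    win = tukey(n, _TUKEY_ALPHA)
    n_fft = int(pad_factor * 2 ** np.ceil(np.log2(n)))
    amp = np.abs(rfft(p * win[None, :], n=n_fft, axis=1)) * dt
    return Spectrum(rfftfreq(n_fft, dt), amp, pad_factor=pad_factor)


@dataclass
class ResonancePeak:
    """Resonance-line measurement: local peak in a band, noise-flagged."""

    frequency: float
    amplitude: float
    detected: bool
    noise_floor: float


def resonance_amplitude(
    spec: Spectrum,
    f_res: float,
    bandwidth: float = 0.4e6,
    detector_index: int = 0,
) -> ResonancePeak:
    """Peak spectral magnitude within ±bandwidth/2 of the expected line.

    The peak must exceed the noise floor (5× the median magnitude in the
    2.5-4 MHz sideband) to count as detected; otherwise the amplitude is
    flagged zero — the "no signal" outcome when the beam stops short of
    the marker.
    """
    if not (spec.freqs[0] <= f_res <= spec.freqs[-1]):
        raise ValueError("f_res outside the spectrum range")
    a = spec.amplitude[detector_index]
    band = (spec.freqs >= f_res - bandwidth / 2) & (spec.freqs <= f_res + bandwidth / 2)
    side = (spec.freqs >= _NOISE_BAND[0]) & (spec.freqs <= _NOISE_BAND[1])
    noise = _NOISE_FLOOR_FACTOR * float(np.median(a[side])) if side.any() else 0.0
    i_peak = np.argmax(a[band])
    f_peak = spec.freqs[band][i_peak]
    a_peak = float(a[band][i_peak])
    if a_peak <= noise:
        return ResonancePeak(float(f_peak), 0.0, False, noise)
    return ResonancePeak(float(f_peak), a_peak, True, noise)


@dataclass
class BipolarMetrics:
    """Extrema of a bipolar waveform and their separation."""

    t_positive: float
    t_negative: float
    peak_to_peak_time: float
    max_abs_pressure: float
    flagged: bool


def bipolar_metrics(trace: PressureTrace, detector_index: int = 0) -> BipolarMetrics:
    """Locate the global positive and negative pressure extrema.

    The pencil-beam waveform is bipolar (compression then rarefaction);
    the extremum separation reflects the lateral beam size.  A trace
    without a genuine sign change is flagged.
    """
    p = trace.pressure[detector_index]
    t = trace.times
    i_pos = int(np.argmax(p))
    i_neg = int(np.argmin(p))
    flagged = p[i_pos] <= 0 or p[i_neg] >= 0
    return BipolarMetrics(
        t_positive=float(t[i_pos]),
        t_negative=float(t[i_neg]),
        peak_to_peak_time=float(abs(t[i_neg] - t[i_pos])),
        max_abs_pressure=float(np.abs(p).max()),
        flagged=flagged,
    )


def trace_difference(with_marker: PressureTrace, without: PressureTrace) -> PressureTrace:
    """Elementwise difference of two runs: isolates the marker component."""
    if not with_marker.same_axes(without):
        raise ValueError("traces have mismatched time axes or detectors")
    return PressureTrace(
        with_marker.times,
        with_marker.pressure - without.pressure,
        with_marker.detector_positions_mm,
    )
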