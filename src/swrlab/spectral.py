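"""LFP spectral pipeline: notch, band-limiting, normalized spectra, band power.

The pipeline mirrors a standard hippocampal oscillation analysis: the
continuous LFP is notch-filtered at 60 Hz, band-limited to 0–100 Hz, and
its power spectrum over 0–100 Hz is normalized to sum to 1, so theta
(4–12 Hz) and low-gamma (30–55 Hz) band powers are dimensionless
fractions of total low-frequency power.  Session band powers can be
divided by a baseline trial's to give a baseline ratio.

All filters are zero-phase (forward-backward application), preserving
event timing for downstream envelope work.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal as sps

from swrlab.types import BandPower, LfpTrace, PowerSpectrum

#: Welch estimator defaults: 2 s Hann segments, 50 % overlap.  Long enough
#: to resolve the 4 Hz theta edge, short enough to average ~300 segments
#: over a 5-min trial.
WELCH_SEGMENT_S = 2.0

SPECTRUM_MAX_HZ = 100.0


class DegenerateInputError(ValueError):
    """Spectral normalization is undefined for an (all-zero) input."""


def _with_samples(trace: LfpTrace, samples: np.ndarray) -> LfpTrace:
    return dataclasses.replace(trace, samples=samples)


def notch_60(trace: LfpTrace, quality: float = 30.0) -> LfpTrace:
    """Remove 60 Hz line noise with a zero-phase IIR notch.

    Quality factor 30 gives a −3 dB bandwidth of 2 Hz; frequencies more
    than 5 Hz from the line are attenuated by well under 1 dB.
    """
    if trace.sampling_rate <= 120.0:
        raise ValueError("sampling rate must exceed 120 Hz to notch 60 Hz")
    b, a = sps.iirnotch(60.0, quality, fs=trace.sampling_rate)
    return _with_samples(trace, sps.filtfilt(b, a, trace.samples))


def band_filter(trace: LfpTrace, lo: float, hi: float, order: int = 4) -> LfpTrace:
    """Zero-phase Butterworth band-pass (low-pass when ``lo`` is 0).

    A 0 Hz lower edge means low-pass filtering; the mean is removed
    explicitly since a true 0 Hz edge is a no-op beyond DC.
    """
    nyq = trace.sampling_rate / 2.0
    if not (0.0 <= lo < hi):
        raise ValueError("need 0 <= lo < hi")
    if hi >= nyq:
        raise ValueError(f"upper edge {hi} Hz must be below Nyquist ({nyq} Hz)")
    x = trace.samples - trace.samples.mean()
    if lo == 0.0:
        sos = sps.butter(order, hi, btype="low", fs=trace.sampling_rate, output="sos")
    else:
        sos = sps.butter(order, [lo, hi], btype="band", fs=trace.sampling_rate, output="sos")
    return _with_samples(trace, sps.sosfiltfilt(sos, x))


def preprocess(trace: LfpTrace) -> LfpTrace:
    """Standard conditioning for spectral analysis: notch then 0–100 Hz."""
    return band_filter(notch_60(trace), 0.0, SPECTRUM_MAX_HZ)


def normalized_spectrum(trace: LfpTrace, segment_s: float = WELCH_SEGMENT_S) -> PowerSpectrum:
    """Welch power spectrum on [0, 100] Hz, normalized to unit sum.

    The trace should already be notch-filtered and band-limited to
    0–100 Hz (see :func:`preprocess`).  Raises
    :class:`DegenerateInputError` for an all-zero trace, where the
    normalization is undefined.
    """
    nperseg = int(round(segment_s * trace.sampling_rate))
    nperseg = min(nperseg, trace.samples.size)
    freqs, pxx = sps.welch(
        trace.samples,
        fs=trace.sampling_rate,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
    )
    keep = freqs <= SPECTRUM_MAX_HZ
    freqs, pxx = freqs[keep], pxx[keep]
    total = pxx.sum()
    if total <= 0.0:
        raise DegenerateInputError("all-zero trace: normalized spectrum undefined")
    return PowerSpectrum(frequencies=freqs, power=pxx / total)


def band_power(
    spectrum: PowerSpectrum, lo: float, hi: float, label: str | None = None
) -> BandPower:
    """Sum normalized power over bins with ``lo <= f < hi``.

    The half-open convention makes disjoint bands tiling [0, 100) a
    partition of unity.
    """
    if not (0.0 <= lo <= hi <= SPECTRUM_MAX_HZ):
        raise ValueError("band must lie within [0, 100] Hz with lo <= hi")
    mask = (spectrum.frequencies >= lo) & (spectrum.frequencies < hi)
    return BandPower(
        label=label or f"{lo:g}-{hi:g}Hz",
        lo=lo,
        hi=hi,
        power=float(spectrum.power[mask].sum()),
    )


def baseline_normalize(session: BandPower, baseline: BandPower) -> float:
    """Session band power divided by the baseline trial's band power."""
    if baseline.power <= 0.0:
        raise ZeroDivisionError("baseline band power is zero; ratio undefined")
    return session.power / baseline.power
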