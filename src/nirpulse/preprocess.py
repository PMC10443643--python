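"""AC/DC decomposition and normalization of raw optical channels.

The raw intensity is split into a cardiac-frequency pulsatile (AC) component
— 2nd-order Butterworth band-pass, 0.8–10 Hz — and a slowly varying baseline
(DC) component — 2nd-order Butterworth low-pass, 0.1 Hz.  The normalized
pulsatile signal consumed downstream is ``ac / dc * 10`` (dimensionless).

Filters are applied forward-backward (zero-phase): morphology features depend
on timing, and phase distortion would bias rise/decay times.  Zero-phase
application squares the magnitude response, so the effective attenuation at
each cutoff is 6 dB.  All filtering happens on the signal undersampled to a
common 100 Hz rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .recording import OpticalRecording

AC_BAND_HZ = (0.8, 10.0)
DC_CUTOFF_HZ = 0.1
FILTER_ORDER = 2
TARGET_RATE_HZ = 100.0

#: seconds at each end of a filtered record considered unreliable
#: (filter settling; 3 periods of the lowest AC cutoff)
EDGE_GUARD_S = 3.0 / AC_BAND_HZ[0]


def undersample(x: np.ndarray, rate_hz: float, target_hz: float = TARGET_RATE_HZ):
    """Resample ``x`` from ``rate_hz`` down to ``target_hz``.

    Uses polyphase resampling with an anti-alias FIR filter; no upsampling
    above the original rate is allowed.  Returns ``(resampled, target_hz)``.
    """
    if rate_hz < target_hz:
        raise ValueError(f"cannot upsample: rate {rate_hz} Hz < target {target_hz} Hz")
    x = np.asarray(x, dtype=float)
    if np.isclose(rate_hz, target_hz):
        return x.copy(), float(rate_hz)
    ratio = Fraction(target_hz).limit_denominator(10000) / Fraction(rate_hz).limit_denominator(
        10000
    )
    y = sps.resample_poly(x, ratio.numerator, ratio.denominator, padtype="line")
    return y, float(target_hz)


def design_ac_filter(rate_hz: float) -> np.ndarray:
    """Second-order Butterworth band-pass (0.8–10 Hz) as SOS."""
    if rate_hz <= 2 * AC_BAND_HZ[1]:
        raise ValueError(f"rate {rate_hz} Hz too low for a {AC_BAND_HZ[1]} Hz upper cutoff")
    return sps.butter(FILTER_ORDER, AC_BAND_HZ, btype="bandpass", fs=rate_hz, output="sos")


def design_dc_filter(rate_hz: float) -> np.ndarray:
    """Second-order Butterworth low-pass (0.1 Hz) as SOS."""
    if rate_hz <= 2 * DC_CUTOFF_HZ:
        raise ValueError(f"rate {rate_hz} Hz too low for a {DC_CUTOFF_HZ} Hz cutoff")
    return sps.butter(FILTER_ORDER, DC_CUTOFF_HZ, btype="lowpass", fs=rate_hz, output="sos")


def extract_ac(x: np.ndarray, rate_hz: float) -> np.ndarray:
    """Zero-phase band-pass: the pulsatile component, same length as input."""
    if rate_hz <= 20:
        raise ValueError("rate_hz must exceed 20 Hz (Nyquist above the 10 Hz cutoff)")
    return sps.sosfiltfilt(design_ac_filter(rate_hz), np.asarray(x, dtype=float))


def extract_dc(x: np.ndarray, rate_hz: float) -> np.ndarray:
    """Zero-phase low-pass: the baseline component, same length as input."""
    if rate_hz <= 0.2:
        raise ValueError("rate_hz must exceed 0.2 Hz (Nyquist above the 0.1 Hz cutoff)")
    return sps.sosfiltfilt(design_dc_filter(rate_hz), np.asarray(x, dtype=float))


def normalize_ppg(ac: np.ndarray, dc: np.ndarray) -> np.ndarray:
    """Elementwise ``ac / dc * 10``.

    ``dc`` must stay above a positivity floor of ``1e-6 * median(|dc|)``
    everywhere; the first offending index is named in the error otherwise.
    """
    ac = np.asarray(ac, dtype=float)
    dc = np.asarray(dc, dtype=float)
    if ac.shape != dc.shape:
        raise ValueError("ac and dc must have the same length")
    floor = 1e-6 * np.median(np.abs(dc))
    bad = np.nonzero(dc <= floor)[0]
    if bad.size:
        raise ValueError(
            f"dc component at/below positivity floor ({floor:g}) first at index {bad[0]}"
        )
    return ac / dc * 10.0


@dataclass
class ACDCDecomposition:
    """AC, DC and normalized components of one channel, all at one rate."""

    ac: np.ndarray
    dc: np.ndarray
    normalized: np.ndarray
    sample_rate_hz: float
    edge_guard_s: float = EDGE_GUARD_S

    def __post_init__(self) -> None:
        if not len(self.ac) == len(self.dc) == len(self.normalized):
            raise ValueError("ac, dc and normalized must share a length")


def decompose(x: np.ndarray, rate_hz: float, target_hz: float = TARGET_RATE_HZ) -> ACDCDecomposition:
    """Undersample one raw channel and split it into AC/DC/normalized."""
    y, rate = undersample(x, rate_hz, target_hz)
    ac = extract_ac(y, rate)
    dc = extract_dc(y, rate)
    return ACDCDecomposition(ac=ac, dc=dc, normalized=normalize_ppg(ac, dc), sample_rate_hz=rate)


def preprocess_recording(
    rec: OpticalRecording, target_hz: float = TARGET_RATE_HZ
) -> dict[str, ACDCDecomposition]:
    """Decompose every channel of a recording; keys are channel names."""
    return {
        name: decompose(rec.samples[name], rec.sample_rate_hz, target_hz)
        for name in sorted(rec.samples)
    }
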