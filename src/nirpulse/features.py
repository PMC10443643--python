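"""Beat detection and the nine pulse-morphology features.

Each detected beat runs from one pulse onset (the minimum between systolic
peaks) to the next.  With the beat baseline defined as the straight chord
joining the signal values at onset and end, the features are:

===  =======================================  =====================
F1   amplitude                                normalized units
F2   pulse width at 50% of the amplitude      s
F3   upslope, F1 / F5 (chord slope)           units / s
F4   decay time, peak -> end                  s
F5   rise time, onset -> peak                 s
F6   area under the curve (= F7 + F8)         units * s
F7   systolic area (onset -> peak)            units * s
F8   diastolic area (peak -> end)             units * s
F9   systolic / diastolic area ratio          dimensionless
===  =======================================  =====================

Areas are trapezoidal over the baseline-corrected pulse with negative
excursions clipped to zero; the systolic/diastolic boundary is the systolic
peak.  Per-feature medians are aggregated over consecutive non-overlapping
windows tiling each protocol section (15 s windows for tilting, 5 s for
Valsalva), and windows with fewer than 3 beats are dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .sectioning import Section

FEATURE_NAMES = ("f1", "f2", "f3", "f4", "f5", "f6", "f7", "f8", "f9")
WINDOW_S = {"tilting": 15.0, "valsalva": 5.0}


class BeatRejected(ValueError):
    """A beat whose features are undefined (flat peak or zero diastolic area)."""


@dataclass(frozen=True)
class Beat:
    """Sample indices of one beat: onset < peak < end, peak maximal."""

    onset_index: int
    peak_index: int
    end_index: int

    def __post_init__(self) -> None:
        if not self.onset_index < self.peak_index < self.end_index:
            raise ValueError("beat must satisfy onset < peak < end")

    def duration_s(self, rate_hz: float) -> float:
        return (self.end_index - self.onset_index) / rate_hz


@dataclass(frozen=True)
class PulseFeatures:
    f1: float
    f2: float
    f3: float
    f4: float
    f5: float
    f6: float
    f7: float
    f8: float
    f9: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES])


@dataclass(frozen=True)
class FeatureRecord:
    """One windowed-median feature vector — a row of the analysis dataset."""

    subject_id: str
    intervention: str
    condition: str
    detector: str
    wavelength_nm: int
    window_index: int
    features: PulseFeatures


def detect_beats(
    normalized: np.ndarray,
    rate_hz: float,
    hr_max_bpm: float = 180.0,
    prominence_fraction: float = 0.3,
    edge_guard_s: float = 0.0,
) -> list[Beat]:
    """Segment the normalized pulse signal into beats.

    Systolic peaks are local maxima separated by at least ``60 / hr_max_bpm``
    seconds with prominence at least ``prominence_fraction`` times the median
    peak prominence; onsets are the minima between consecutive peaks.  The
    first and last partial beats are discarded, as are peaks within
    ``edge_guard_s`` of the record ends (filter settling).  Fewer than two
    usable peaks yields an empty list.
    """
    x = np.asarray(normalized, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")
    if rate_hz < 20:
        raise ValueError("rate_hz must be at least 20 Hz for beat detection")
    if len(x) < 2 * rate_hz:
        raise ValueError("signal must be at least 2 s long")

    distance = max(1, int(round(rate_hz * 60.0 / hr_max_bpm)))
    peaks, props = sps.find_peaks(x, distance=distance, prominence=0.0)
    if len(peaks) < 2:
        return []
    prom = props["prominences"]
    peaks = peaks[prom >= prominence_fraction * np.median(prom)]
    if edge_guard_s > 0:
        guard = int(round(edge_guard_s * rate_hz))
        peaks = peaks[(peaks >= guard) & (peaks < len(x) - guard)]
    if len(peaks) < 3:
        return []

    minima = np.array(
        [p0 + int(np.argmin(x[p0:p1])) for p0, p1 in zip(peaks[:-1], peaks[1:])]
    )
    beats = []
    for k in range(1, len(peaks) - 1):
        onset, end = minima[k - 1], minima[k]
        peak = onset + int(np.argmax(x[onset : end + 1]))
        if onset < peak < end:
            beats.append(Beat(onset, peak, end))
    return beats


def extract_pulse_features(
    normalized: np.ndarray, beat: Beat, rate_hz: float
) -> PulseFeatures:
    """Compute F1–F9 for one beat; raises ``BeatRejected`` for degenerate beats."""
    x = np.asarray(normalized, dtype=float)
    o, p, e = beat.onset_index, beat.peak_index, beat.end_index
    if e >= len(x):
        raise ValueError("beat indices exceed signal length")
    duration = (e - o) / rate_hz
    if duration < 0.25:
        raise ValueError("beat shorter than 0.25 s")

    # baseline correction by the onset-to-end chord
    idx = np.arange(o, e + 1)
    baseline = x[o] + (x[e] - x[o]) * (idx - o) / (e - o)
    y = x[o : e + 1] - baseline
    pk = p - o

    f1 = y[pk]
    if f1 <= 0:
        raise BeatRejected("peak not above the onset-end chord")
    f5 = pk / rate_hz
    f4 = (e - p) / rate_hz
    f3 = f1 / f5
    f2 = _half_height_width(y, pk, rate_hz, f1)

    yc = np.clip(y, 0.0, None)
    f7 = float(np.trapezoid(yc[: pk + 1], dx=1.0 / rate_hz))
    f8 = float(np.trapezoid(yc[pk:], dx=1.0 / rate_hz))
    f6 = f7 + f8
    if f8 <= 0:
        raise BeatRejected("zero diastolic area; ratio undefined")
    f9 = f7 / f8
    return PulseFeatures(float(f1), f2, float(f3), f4, f5, f6, f7, f8, float(f9))


def _half_height_width(y: np.ndarray, pk: int, rate_hz: float, amplitude: float) -> float:
    """Width of the baseline-corrected pulse at 50% of its amplitude."""
    half = 0.5 * amplitude
    rising = y[: pk + 1]
    below = np.nonzero(rising < half)[0]
    if below.size == 0:  # pulse starts at/above half height (pk == 0 excluded by caller)
        t_rise = 0.0
    else:
        j = below[-1]
        if j == pk:
            t_rise = float(pk)
        else:
            t_rise = j + (half - rising[j]) / (rising[j + 1] - rising[j])
    falling = y[pk:]
    below = np.nonzero(falling < half)[0]
    if below.size == 0:  # never decays below half before the beat ends
        t_fall = float(len(y) - 1)
    else:
        j = below[0]
        prev = falling[j - 1] if j > 0 else falling[j]
        frac = 0.0 if prev == falling[j] else (prev - half) / (prev - falling[j])
        t_fall = pk + (j - 1) + frac
    return max(t_fall - t_rise, 0.0) / rate_hz


def windowed_medians(
    beats_features: list[tuple[float, PulseFeatures]],
    section: Section,
    window_s: float,
    rate_hz: float,
    *,
    subject_id: str = "",
    intervention: str = "tilting",
    detector: str = "distal",
    wavelength_nm: int = 810,
    min_beats: int = 3,
) -> list[FeatureRecord]:
    """Tile a section with windows of ``window_s`` and take per-feature medians.

    Beats are assigned to windows by systolic-peak time; windows with fewer
    than ``min_beats`` beats (and the trailing partial window) are dropped.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    if not beats_features:
        return []
    times = np.array([t for t, _ in beats_features])
    if np.any(np.diff(times) < 0):
        raise ValueError("beat features must be sorted by time")
    matrix = np.vstack([pf.as_array() for _, pf in beats_features])

    start_s = section.start_index / rate_hz
    end_s = section.end_index / rate_hz
    n_windows = int((end_s - start_s) / window_s)
    records = []
    for w in range(n_windows):
        lo = start_s + w * window_s
        hi = lo + window_s
        mask = (times >= lo) & (times < hi)
        if mask.sum() < min_beats:
            continue
        med = np.median(matrix[mask], axis=0)
        records.append(
            FeatureRecord(
                subject_id=subject_id,
                intervention=intervention,
                condition=section.label,
                detector=detector,
                wavelength_nm=wavelength_nm,
                window_index=w,
                features=PulseFeatures(*med),
            )
        )
    return records


@dataclass
class SectionedChannel:
    """One preprocessed channel plus its protocol sections — feature-table input."""

    subject_id: str
    intervention: str
    detector: str
    wavelength_nm: int
    normalized: np.ndarray
    rate_hz: float
    sections: list[Section]


def beats_with_features(
    normalized: np.ndarray,
    rate_hz: float,
    edge_guard_s: float = 0.0,
) -> list[tuple[float, PulseFeatures]]:
    """Detect beats and extract per-beat features, silently dropping rejects."""
    out = []
    for beat in detect_beats(normalized, rate_hz, edge_guard_s=edge_guard_s):
        try:
            pf = extract_pulse_features(normalized, beat, rate_hz)
        except (BeatRejected, ValueError):
            continue
        out.append((beat.peak_index / rate_hz, pf))
    return out


def build_feature_table(
    items: list[SectionedChannel],
    window_s: float | None = None,
    edge_guard_s: float = 0.0,
) -> pd.DataFrame:
    """Assemble the tidy analysis table across subjects, channels and sections.

    Rows are ordered by (subject, detector, wavelength, section, window); a
    channel that yields no valid beats in any section is reported with a
    warning and skipped.
    """
    rows: list[FeatureRecord] = []
    ordered = sorted(items, key=lambda it: (it.subject_id, it.detector, it.wavelength_nm))
    for item in ordered:
        ws = window_s if window_s is not None else WINDOW_S[item.intervention]
        feats = beats_with_features(item.normalized, item.rate_hz, edge_guard_s)
        produced = []
        for section in item.sections:
            if section.label == "transition":
                continue
            produced.extend(
                windowed_medians(
                    feats,
                    section,
                    ws,
                    item.rate_hz,
                    subject_id=item.subject_id,
                    intervention=item.intervention,
                    detector=item.detector,
                    wavelength_nm=item.wavelength_nm,
                )
            )
        if not produced:
            warnings.warn(
                f"no valid beats for subject {item.subject_id!r} channel "
                f"{item.detector}_{item.wavelength_nm}; channel skipped",
                stacklevel=2,
            )
            continue
        rows.extend(produced)
    return records_to_frame(rows)


def records_to_frame(records: list[FeatureRecord]) -> pd.DataFrame:
    data = {
        "subject": [r.subject_id for r in records],
        "intervention": [r.intervention for r in records],
        "condition": [r.condition for r in records],
        "detector": [r.detector for r in records],
        "wavelength_nm": [r.wavelength_nm for r in records],
        "window_index": [r.window_index for r in records],
    }
    arr = (
        np.vstack([r.features.as_array() for r in records])
        if records
        else np.empty((0, len(FEATURE_NAMES)))
    )
    for j, name in enumerate(FEATURE_NAMES):
        data[name] = arr[:, j]
    return pd.DataFrame(data)
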