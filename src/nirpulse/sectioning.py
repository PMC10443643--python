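"""Protocol sectioning: labeled condition segments of the normalized signal.

Two algorithms, matching the two intervention protocols:

* **tilting** — body-position changes are known by time.  The average
  transition duration is recovered from the total record length (total minus
  the nominal position durations, divided by the number of transitions), the
  three position windows are laid out around the transitions, and the middle
  ``keep_fraction`` (default 60%) of each window is kept so that only stable
  data enter the analysis.

* **valsalva** — maneuvers are not time-locked, so events are found from the
  signal itself: the first derivative of the normalized pulse signal is
  smoothed (Savitzky-Golay), its upper/lower envelopes are interpolated
  through beat-scale extrema, the three largest well-separated envelope
  maxima mark strain onsets and the deepest following envelope minima mark
  releases, and each window boundary snaps to the nearest crossing of the
  first and second derivatives.  The baseline segment has the mean event
  duration and ends a guard gap before the first event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

TILTING_LABELS = ("supine1", "trendelenburg", "supine2")
VALSALVA_LABELS = ("baseline", "valsalva1", "valsalva2", "valsalva3")


@dataclass(frozen=True)
class ProtocolTiming:
    """Nominal tilting-protocol layout."""

    nominal_durations_s: tuple[float, ...] = (300.0, 300.0, 120.0)
    n_transitions: int = 2
    keep_fraction: float = 0.6
    labels: tuple[str, ...] = TILTING_LABELS

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.nominal_durations_s):
            raise ValueError("nominal durations must be positive")
        if not 0 < self.keep_fraction <= 1:
            raise ValueError("keep_fraction must lie in (0, 1]")
        if len(self.labels) != len(self.nominal_durations_s):
            raise ValueError("one label per nominal duration required")


@dataclass(frozen=True)
class Section:
    """A labeled half-open sample interval [start_index, end_index)."""

    label: str
    start_index: int
    end_index: int

    def __post_init__(self) -> None:
        if not 0 <= self.start_index < self.end_index:
            raise ValueError(f"invalid section bounds for {self.label!r}")

    @property
    def n_samples(self) -> int:
        return self.end_index - self.start_index

    def start_s(self, rate_hz: float) -> float:
        return self.start_index / rate_hz

    def end_s(self, rate_hz: float) -> float:
        return self.end_index / rate_hz


def _check_disjoint(sections: list[Section], signal_length: int) -> None:
    prev_end = 0
    for sec in sections:
        if sec.start_index < prev_end:
            raise ValueError("sections must be disjoint and ordered")
        if sec.end_index > signal_length:
            raise ValueError("section exceeds signal bounds")
        prev_end = sec.end_index


def section_tilting(
    signal_length: int, rate_hz: float, timing: ProtocolTiming = ProtocolTiming()
) -> list[Section]:
    """Time-based sectioning of a tilting recording.

    The average transition time is ``t = (duration - sum(nominal)) /
    n_transitions``; position windows are laid out with one transition
    inserted between consecutive positions, and each returned section is the
    middle ``keep_fraction`` of its window.
    """
    total_s = signal_length / rate_hz
    nominal = timing.nominal_durations_s
    slack = total_s - sum(nominal)
    if slack < -0.5 / rate_hz:
        raise ValueError(
            f"recording ({total_s:.1f} s) shorter than the nominal protocol "
            f"({sum(nominal):.1f} s): negative transition time"
        )
    t = max(slack, 0.0) / timing.n_transitions

    sections = []
    cursor = 0.0
    trim = (1.0 - timing.keep_fraction) / 2.0
    for i, (label, dur) in enumerate(zip(timing.labels, nominal)):
        w0, w1 = cursor, cursor + dur
        s0 = w0 + trim * dur
        s1 = w1 - trim * dur
        sections.append(
            Section(label, int(round(s0 * rate_hz)), int(round(s1 * rate_hz)))
        )
        cursor = w1 + (t if i < len(nominal) - 1 else 0.0)
    _check_disjoint(sections, signal_length)
    return sections


# ---------------------------------------------------------------------------
# Valsalva: derivative envelopes

def derivative_envelope(
    normalized: np.ndarray,
    rate_hz: float,
    window_s: float = 0.51,
    polyorder: int = 3,
    extrema_sep_s: float = 0.4,
):
    """Smoothed first/second derivatives and the envelopes of the first.

    Returns ``(d1, d2, env_upper, env_lower)``.  Derivatives are discrete
    gradients smoothed with a Savitzky-Golay filter; the envelopes linearly
    interpolate through local extrema of ``d1`` separated by at least
    ``extrema_sep_s`` (a beat-scale neighborhood).
    """
    x = np.asarray(normalized, dtype=float)
    window = int(round(window_s * rate_hz))
    if window % 2 == 0:
        window += 1
    if window <= polyorder:
        raise ValueError("Savitzky-Golay window must exceed the polynomial order")
    if len(x) <= window:
        raise ValueError("signal shorter than the smoothing window")

    d1 = sps.savgol_filter(np.gradient(x) * rate_hz, window, polyorder)
    d2 = sps.savgol_filter(np.gradient(d1) * rate_hz, window, polyorder)

    sep = max(1, int(round(extrema_sep_s * rate_hz)))
    idx = np.arange(len(x))

    def _envelope(y: np.ndarray) -> np.ndarray:
        peaks, _ = sps.find_peaks(y, distance=sep)
        if len(peaks) < 2:
            return np.full_like(y, y.max())
        return np.interp(idx, peaks, y[peaks])

    return d1, d2, _envelope(d1), -_envelope(-d1)


@dataclass(frozen=True)
class ValsalvaParams:
    """Tunables of the Valsalva event detector (defaults are beat/protocol scale)."""

    n_events: int = 3
    min_event_sep_s: float = 10.0     # minimum spacing between detected strain onsets
    closeness_s: float = 2.0          # envelope extremum <-> derivative crossing tolerance
    guard_s: float = 5.0              # gap between baseline end and first event
    min_event_s: float = 5.0          # a release is searched at least this far after onset
    max_event_s: float = 25.0         # ... and at most this far (maneuver-scale bound)
    rel_height: float = 1.8           # event extrema must exceed this multiple of the
                                      # median envelope magnitude
    boundary_guard_s: float = 4.0     # ignore extrema this close to the record ends
                                      # (zero-phase filter settling)
    sg_window_s: float = 0.51
    sg_polyorder: int = 3
    extrema_sep_s: float = 0.4


def _nearest_crossing(crossings: np.ndarray, idx: int, tol_samples: float) -> int:
    """Index of the d1/d2 crossing nearest ``idx`` (fallback: ``idx`` itself)."""
    if crossings.size == 0:
        return idx
    j = crossings[np.argmin(np.abs(crossings - idx))]
    return int(j) if abs(j - idx) <= tol_samples else idx


def section_valsalva(
    normalized: np.ndarray,
    rate_hz: float,
    params: ValsalvaParams = ValsalvaParams(),
) -> list[Section]:
    """Detect the three Valsalva windows plus a matched baseline segment.

    Raises ``ValueError("insufficient events: ...")`` when fewer than
    ``params.n_events`` qualifying envelope maxima/minima are found, and when
    the baseline segment would start before the record does.
    """
    x = np.asarray(normalized, dtype=float)
    d1, d2, env_u, env_l = derivative_envelope(
        x, rate_hz, params.sg_window_s, params.sg_polyorder, params.extrema_sep_s
    )

    # Candidate strain onsets: envelope maxima, highest first, ignoring the
    # zero-phase filter-settling zones at the record ends.
    sep = max(1, int(round(params.min_event_sep_s * rate_hz)))
    guard = int(round(params.boundary_guard_s * rate_hz))
    maxima, _ = sps.find_peaks(env_u, distance=sep)
    maxima = maxima[(maxima >= guard) & (maxima < len(x) - guard)]
    height_threshold = params.rel_height * np.median(env_u)
    maxima = maxima[env_u[maxima] >= height_threshold]
    maxima = maxima[np.argsort(env_u[maxima])[::-1]]

    depth_threshold = params.rel_height * np.median(np.abs(env_l))
    min_gap = int(round(params.min_event_s * rate_hz))
    max_gap = int(round(params.max_event_s * rate_hz))

    # Greedy pairing: accept an onset candidate only if a qualifying release
    # (deep env_lower minimum) follows within the maneuver-scale span and the
    # resulting window does not collide with an already accepted one.
    accepted: list[tuple[int, int]] = []
    for m in maxima:
        if len(accepted) == params.n_events:
            break
        if any(abs(int(m) - a) < sep for a, _ in accepted):
            continue
        lo, hi = int(m) + min_gap, min(int(m) + max_gap, len(x) - guard)
        if hi - lo < 2:
            continue
        seg = env_l[lo:hi]
        rel_min, _ = sps.find_peaks(-seg)
        if rel_min.size == 0:
            rel_min = np.array([int(np.argmin(seg))])
        low = lo + int(rel_min[np.argmin(seg[rel_min])])
        if -env_l[low] < depth_threshold:
            continue
        if any(int(m) < e and low > s for s, e in accepted):
            continue
        accepted.append((int(m), low))
    if len(accepted) < params.n_events:
        raise ValueError(
            "insufficient events: fewer than "
            f"{params.n_events} qualifying envelope maximum/minimum pairs"
        )
    accepted.sort()

    # d1/d2 crossings (sign changes of d1 - d2) are beat-dense; boundaries snap
    # to the one nearest each envelope extremum.
    z = d1 - d2
    crossings = np.nonzero(np.diff(np.sign(z)) != 0)[0]
    tol = params.closeness_s * rate_hz
    windows: list[tuple[int, int]] = []
    for m, low in accepted:
        start = _nearest_crossing(crossings, m, tol)
        end = _nearest_crossing(crossings, low, tol)
        if end <= start:
            raise ValueError("insufficient events: degenerate event window")
        windows.append((start, end))

    durations = [e - s for s, e in windows]
    baseline_len = int(round(float(np.mean(durations))))
    baseline_end = windows[0][0] - int(round(params.guard_s * rate_hz))
    baseline_start = baseline_end - baseline_len
    if baseline_start < 0:
        raise ValueError("baseline segment would start before the recording does")

    sections = [Section("baseline", baseline_start, baseline_end)] + [
        Section(f"valsalva{i + 1}", s, e) for i, (s, e) in enumerate(windows)
    ]
    _check_disjoint(sections, len(x))
    return sections


# ---------------------------------------------------------------------------
# serialization

def sections_to_frame(sections: list[Section], rate_hz: float) -> pd.DataFrame:
    """BED-like table: label, start/end sample, start/end seconds."""
    return pd.DataFrame(
        {
            "label": [s.label for s in sections],
            "start_sample": [s.start_index for s in sections],
            "end_sample": [s.end_index for s in sections],
            "start_s": [s.start_s(rate_hz) for s in sections],
            "end_s": [s.end_s(rate_hz) for s in sections],
        }
    )


def write_sections(sections: list[Section], rate_hz: float, path) -> None:
    sections_to_frame(sections, rate_hz).to_csv(path, sep="\t", index=False)


def read_sections(path) -> list[Section]:
    df = pd.read_csv(path, sep="\t")
    return [
        Section(row.label, int(row.start_sample), int(row.end_sample))
        for row in df.itertuples()
    ]
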