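"""Containers and plain-text I/O for multi-channel forehead optical recordings.

A recording holds raw light-intensity samples from a reflectance-mode forehead
probe with two photodiodes: a *proximal* detector (10 mm from the emitters,
interrogating mostly extracerebral tissue) and a *distal* detector (35 mm,
reaching deeper, cerebral tissue).  Each detector may be sampled at one or more
near-infrared wavelengths; downstream analysis uses the 810 nm isosbestic
channel, where oxy- and deoxyhemoglobin absorb equally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DETECTORS = ("proximal", "distal")
WAVELENGTHS_NM = (770, 810, 855, 880)
INTERVENTIONS = ("tilting", "valsalva")


@dataclass(frozen=True)
class Channel:
    """One (detector, wavelength) acquisition channel."""

    detector: str
    wavelength_nm: int

    def __post_init__(self) -> None:
        if self.detector not in DETECTORS:
            raise ValueError(f"unknown detector {self.detector!r}; expected one of {DETECTORS}")
        if self.wavelength_nm not in WAVELENGTHS_NM:
            raise ValueError(
                f"unknown wavelength {self.wavelength_nm}; expected one of {WAVELENGTHS_NM}"
            )

    @property
    def name(self) -> str:
        return f"{self.detector}_{self.wavelength_nm}"

    @classmethod
    def from_name(cls, name: str) -> "Channel":
        detector, _, wl = name.rpartition("_")
        return cls(detector=detector, wavelength_nm=int(wl))


@dataclass
class OpticalRecording:
    """Multi-channel sampled light intensities plus acquisition metadata.

    ``samples`` maps channel names (e.g. ``"distal_810"``) to 1-D float arrays
    of equal length; intensities are in arbitrary units.
    """

    samples: dict[str, np.ndarray]
    sample_rate_hz: float
    channels: list[Channel]
    subject_id: str
    intervention: str

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.intervention not in INTERVENTIONS:
            raise ValueError(f"intervention must be one of {INTERVENTIONS}")
        names = {c.name for c in self.channels}
        if names != set(self.samples):
            raise ValueError("channel metadata does not match sample keys")
        lengths = {len(v) for v in self.samples.values()}
        if len(lengths) != 1:
            raise ValueError("all channels must have equal length")
        for key in self.samples:
            self.samples[key] = np.asarray(self.samples[key], dtype=float)

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.samples.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def channel(self, detector: str, wavelength_nm: int = 810) -> np.ndarray:
        return self.samples[Channel(detector, wavelength_nm).name]

    # -- plain-text I/O ----------------------------------------------------

    def to_csv(self, path: str | Path, float_format: str = "%.6f") -> None:
        """Write as CSV with a ``time_s`` column plus one column per channel."""
        t = np.arange(self.n_samples) / self.sample_rate_hz
        cols = {"time_s": t}
        for ch in sorted(self.channels, key=lambda c: c.name):
            cols[ch.name] = self.samples[ch.name]
        pd.DataFrame(cols).to_csv(path, index=False, float_format=float_format)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        subject_id: str = "",
        intervention: str = "tilting",
        sample_rate_hz: float | None = None,
    ) -> "OpticalRecording":
        df = pd.read_csv(path)
        if "time_s" not in df.columns:
            raise ValueError("recording CSV must contain a time_s column")
        if sample_rate_hz is None:
            dt = np.median(np.diff(df["time_s"].to_numpy()))
            sample_rate_hz = float(round(1.0 / dt, 6))
        names = [c for c in df.columns if c != "time_s"]
        channels = [Channel.from_name(n) for n in names]
        samples = {n: df[n].to_numpy(dtype=float) for n in names}
        return cls(samples, sample_rate_hz, channels, subject_id, intervention)


@dataclass
class SyntheticGroundTruth:
    """Ground truth emitted alongside a synthetic recording.

    ``true_sections`` is an ordered list of ``(label, start_s, end_s)`` with
    disjoint intervals; ``beat_times`` maps detector name to the systolic-peak
    times in seconds; ``applied_multipliers`` maps detector name to the
    per-feature multiplicative effects actually applied in the affected
    condition.
    """

    true_sections: list[tuple[str, float, float]]
    beat_times: dict[str, np.ndarray]
    applied_multipliers: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for label, start, end in self.true_sections:
            if not start < end:
                raise ValueError(f"section {label!r} has non-positive length")
            if start < prev_end:
                raise ValueError("true sections must be disjoint and ordered")
            prev_end = end
        for det, times in self.beat_times.items():
            times = np.asarray(times, dtype=float)
            if np.any(np.diff(times) <= 0):
                raise ValueError(f"beat times for {det!r} must be strictly increasing")
            self.beat_times[det] = times

    def sections_labeled(self, label: str) -> list[tuple[float, float]]:
        return [(s, e) for lab, s, e in self.true_sections if lab == label]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "true_sections": [
                {"label": lab, "start_s": s, "end_s": e} for lab, s, e in self.true_sections
            ],
            "beat_times": {k: np.round(v, 6).tolist() for k, v in sorted(self.beat_times.items())},
            "applied_multipliers": self.applied_multipliers,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticGroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            true_sections=[
                (d["label"], d["start_s"], d["end_s"]) for d in payload["true_sections"]
            ],
            beat_times={k: np.asarray(v) for k, v in payload["beat_times"].items()},
            applied_multipliers=payload.get("applied_multipliers", {}),
        )
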