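"""Seeded generator of two-channel forehead pulse recordings.

The generator emulates the statistical structure the analysis pipeline
assumes, for two intervention protocols that raise intracranial pressure:

* **tilting** — supine (5 min) -> Trendelenburg −30° (5 min) -> supine
  (2 min), with 30–60 s transitions between positions during which the
  baseline (DC) intensity ramps linearly;
* **valsalva** — a seated baseline followed by three strain maneuvers during
  which the DC level ramps up transiently and the pulse morphology changes.

Each cardiac pulse is a smooth two-lobe template (a systolic and a smaller
diastolic raised-cosine lobe) riding on a slowly drifting DC baseline with
additive Gaussian noise.  In the affected condition the *distal* channel's
per-beat morphology is scaled by configurable multipliers (amplitude, width),
while the *proximal* channel receives the same effects attenuated by a single
factor — modelling that only the distal detector sees cerebral tissue.

All randomness flows through one ``numpy`` generator seeded from
``(config.seed, subject_id)``; identical inputs give bitwise-identical output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .recording import Channel, OpticalRecording, SyntheticGroundTruth

__all__ = [
    "PulseMorphology",
    "SynthConfig",
    "beat_waveform",
    "generate_tilting_recording",
    "generate_valsalva_recording",
    "generate_recording",
]


# ---------------------------------------------------------------------------
# pulse template

@dataclass(frozen=True)
class PulseMorphology:
    """Shape parameters of the single-cycle pulse template.

    The template is the sum of two raised-cosine lobes over phase in [0, 1):
    a systolic lobe centered at ``rise_fraction`` with half-width
    ``rise_fraction * width`` (so it is anchored at zero at phase 0 for
    ``width <= 1``), and a diastolic lobe of relative height
    ``diastolic_ratio`` centered at ``diastolic_center``.  The cycle maximum
    equals ``amplitude`` and occurs at phase ``rise_fraction``; the area under
    one cycle scales linearly with ``width`` as long as both lobes fit inside
    the cycle.
    """

    amplitude: float = 1.0
    width: float = 0.85
    rise_fraction: float = 0.3
    diastolic_ratio: float = 0.3
    diastolic_center: float = 0.6
    diastolic_halfwidth: float = 0.3

    def __post_init__(self) -> None:
        vals = (
            self.amplitude, self.width, self.rise_fraction,
            self.diastolic_ratio, self.diastolic_center, self.diastolic_halfwidth,
        )
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("morphology parameters must be finite")
        if self.width <= 0 or not 0 < self.rise_fraction < 1:
            raise ValueError("width must be positive and rise_fraction in (0, 1)")


def _raised_cosine(phase: np.ndarray, center, halfwidth) -> np.ndarray:
    """cos^2 bump of unit height with compact support |phase-center| < halfwidth."""
    u = (np.asarray(phase, dtype=float) - center) / halfwidth
    out = np.where(np.abs(u) < 1.0, np.cos(0.5 * np.pi * np.clip(u, -1, 1)) ** 2, 0.0)
    return out


def _render_unit(phase, width, rise_fraction, diastolic_ratio,
                 diastolic_center=0.7, diastolic_halfwidth=0.3):
    """Unit-amplitude template; ``phase`` and ``width`` may be arrays."""
    systolic = _raised_cosine(phase, rise_fraction, rise_fraction * width)
    diastolic = _raised_cosine(phase, diastolic_center, diastolic_halfwidth * width)
    return systolic + diastolic_ratio * diastolic


def beat_waveform(phase, morphology: PulseMorphology = PulseMorphology()):
    """Evaluate one sample (or array of samples) of the pulse template.

    ``phase`` must lie in [0, 1).  Returns 0 at phase 0 and reaches its
    maximum, equal to ``morphology.amplitude``, at ``morphology.rise_fraction``.
    """
    phase = np.asarray(phase, dtype=float)
    if np.any(phase < 0) or np.any(phase >= 1):
        raise ValueError("phase must lie in [0, 1)")
    y = morphology.amplitude * _render_unit(
        phase, morphology.width, morphology.rise_fraction,
        morphology.diastolic_ratio, morphology.diastolic_center,
        morphology.diastolic_halfwidth,
    )
    return float(y) if y.ndim == 0 else y


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic world.

    Magnitudes without a stated protocol value (pulse fraction, physiological
    modulation, drift) are fixed stand-ins chosen once for plausibility and
    test stability; see docs/methods.md.
    """

    sample_rate_hz: float = 500.0
    heart_rate_bpm: float = 70.0
    hr_jitter: float = 0.03               # cycle-to-cycle period jitter fraction
    n_subjects: int = 16
    protocol: str = "tilting"
    condition_effects: dict[str, float] = field(
        default_factory=lambda: {"amplitude": 1.3, "width": 1.15}
    )
    proximal_attenuation: float = 0.3     # in (0, 1]
    dc_levels: dict[str, float] = field(
        default_factory=lambda: {"supine": 5.0, "trendelenburg": 5.5, "baseline": 5.0}
    )
    valsalva_dc_ramp: float = 0.15        # fractional DC rise during a maneuver
    noise_sd: float = 0.05                # relative to the baseline pulse amplitude
    transition_range_s: tuple[float, float] = (30.0, 60.0)
    seed: int = 0
    # protocol durations (s)
    supine1_s: float = 300.0
    trendelenburg_s: float = 300.0
    supine2_s: float = 120.0
    baseline_s: float = 60.0
    valsalva_s: float = 15.0
    recovery_s: float = 35.0
    tail_s: float = 20.0
    n_valsalva: int = 3
    valsalva_ramp_s: float = 0.3          # DC rise/release time at maneuver edges
    # pulse and physiology
    pulse_fraction: float = 0.02          # pulse amplitude as a fraction of DC
    morphology: PulseMorphology = PulseMorphology()
    amp_variability: float = 0.08         # respiratory-scale amplitude modulation
    width_variability: float = 0.04
    modulation_freq_hz: float = 0.09
    vlf_variability: float = 0.10         # very-low-frequency (window-scale) modulation
    vlf_freq_hz: float = 0.015
    amp_jitter: float = 0.03              # iid per-beat amplitude jitter
    subject_amp_sd: float = 0.10          # between-subject baseline heterogeneity
    subject_width_sd: float = 0.05
    subject_hr_sd: float = 0.08
    dc_drift: float = 0.01                # relative slow DC drift amplitude
    wavelengths: tuple[int, ...] = (810,)

    def __post_init__(self) -> None:
        positive = {
            "sample_rate_hz": self.sample_rate_hz,
            "heart_rate_bpm": self.heart_rate_bpm,
            "supine1_s": self.supine1_s,
            "trendelenburg_s": self.trendelenburg_s,
            "supine2_s": self.supine2_s,
            "baseline_s": self.baseline_s,
            "valsalva_s": self.valsalva_s,
            "pulse_fraction": self.pulse_fraction,
        }
        for name, v in positive.items():
            if v <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.protocol not in ("tilting", "valsalva"):
            raise ValueError("protocol must be 'tilting' or 'valsalva'")
        if not 0 < self.proximal_attenuation <= 1:
            raise ValueError("proximal_attenuation must lie in (0, 1]")
        for k, v in self.condition_effects.items():
            if v <= 0:
                raise ValueError(f"effect multiplier {k!r} must be strictly positive")
        lo, hi = self.transition_range_s
        if lo < 0 or hi < lo:
            raise ValueError("transition_range_s must satisfy 0 <= lo <= hi")
        if self.noise_sd < 0 or self.hr_jitter < 0:
            raise ValueError("noise_sd and hr_jitter must be non-negative")
        if self.n_valsalva < 1:
            raise ValueError("n_valsalva must be >= 1")


def _subject_key(subject_id: str) -> int:
    return zlib.crc32(str(subject_id).encode())


def _detector_multipliers(config: SynthConfig, detector: str) -> dict[str, float]:
    """Condition multipliers seen by one detector (proximal ones attenuated)."""
    att = 1.0 if detector == "distal" else config.proximal_attenuation
    return {k: 1.0 + att * (m - 1.0) for k, m in config.condition_effects.items()}


def _beat_schedule(rng: np.random.Generator, duration_s: float, config: SynthConfig,
                   heart_rate_bpm: float | None = None):
    base = 60.0 / (heart_rate_bpm or config.heart_rate_bpm)
    n = int(duration_s / base * 1.4) + 8
    eps = np.clip(rng.standard_normal(n), -3, 3)
    periods = base * (1.0 + config.hr_jitter * eps)
    onsets = np.concatenate([[0.0], np.cumsum(periods)[:-1]])
    keep = onsets < duration_s
    return onsets[keep], periods[keep]


def _subject_physiology(rng: np.random.Generator, config: SynthConfig):
    """Per-subject baseline factors: amplitude, width and heart-rate scale."""
    eps = np.clip(rng.standard_normal(3), -2.5, 2.5)
    amp_factor = float(np.exp(config.subject_amp_sd * eps[0]))
    width_factor = float(np.exp(config.subject_width_sd * eps[1]))
    hr = config.heart_rate_bpm * (1.0 + config.subject_hr_sd * np.tanh(eps[2]))
    return amp_factor, width_factor, float(hr)


def _beat_modulation(rng: np.random.Generator, onsets: np.ndarray, config: SynthConfig):
    """Slow physiological modulation of per-beat amplitude/width plus iid jitter.

    Amplitude carries a respiratory-scale and a very-low-frequency (window-
    scale) sinusoidal component; width a respiratory-scale component only.
    Returns ``(slow_amp, slow_width, jitter_amp, drift_phase)``.
    """
    phi = rng.uniform(0, 2 * np.pi, size=4)
    eps = np.clip(rng.standard_normal(len(onsets)), -3, 3)
    slow_a = (
        1.0
        + config.amp_variability * np.sin(2 * np.pi * config.modulation_freq_hz * onsets + phi[0])
        + config.vlf_variability * np.sin(2 * np.pi * config.vlf_freq_hz * onsets + phi[2])
    )
    slow_w = 1.0 + config.width_variability * np.sin(
        2 * np.pi * config.modulation_freq_hz * onsets + phi[1]
    )
    jitter_a = 1.0 + config.amp_jitter * eps
    return slow_a, slow_w, jitter_a, phi[3]


def _render_pulse_train(t, onsets, periods, amps, widths, morph: PulseMorphology):
    k = np.clip(np.searchsorted(onsets, t, side="right") - 1, 0, len(onsets) - 1)
    phase = (t - onsets[k]) / periods[k]
    y = amps[k] * _render_unit(
        phase, widths[k], morph.rise_fraction, morph.diastolic_ratio,
        morph.diastolic_center, morph.diastolic_halfwidth,
    )
    y[(phase < 0) | (phase >= 1)] = 0.0
    return y


def _smoothstep(t: np.ndarray, center: float, ramp_s: float) -> np.ndarray:
    """0 -> 1 smooth transition of width ``ramp_s`` centered at ``center``."""
    if ramp_s <= 0:
        return (t >= center).astype(float)
    u = np.clip((t - (center - 0.5 * ramp_s)) / ramp_s, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _assemble(config, subject_id, samples_by_channel, sections, beat_peaks):
    channels = [
        Channel(det, wl)
        for det in ("distal", "proximal")
        for wl in config.wavelengths
    ]
    rec = OpticalRecording(
        samples=samples_by_channel,
        sample_rate_hz=config.sample_rate_hz,
        channels=channels,
        subject_id=str(subject_id),
        intervention=config.protocol,
    )
    truth = SyntheticGroundTruth(
        true_sections=sections,
        beat_times={"distal": beat_peaks.copy(), "proximal": beat_peaks.copy()},
        applied_multipliers={
            "distal": _detector_multipliers(config, "distal"),
            "proximal": _detector_multipliers(config, "proximal"),
        },
    )
    return rec, truth


# ---------------------------------------------------------------------------
# protocols

def generate_tilting_recording(config: SynthConfig, subject_id: str):
    """Simulate one subject's tilting-protocol recording.

    Returns ``(OpticalRecording, SyntheticGroundTruth)``.  Layout: supine1
    (300 s) -> transition -> Trendelenburg (300 s) -> transition -> supine2
    (120 s); transition durations are drawn uniformly from
    ``config.transition_range_s``.  During Trendelenburg the distal channel's
    per-beat morphology is scaled by ``config.condition_effects`` and the
    proximal channel by the attenuated multipliers; the DC level ramps
    linearly across transitions.
    """
    if config.protocol != "tilting":
        raise ValueError("config.protocol must be 'tilting' for a tilting recording")
    rng = np.random.default_rng([int(config.seed), _subject_key(subject_id)])

    t1, t2 = rng.uniform(*config.transition_range_s, size=2)
    b0 = 0.0
    b1 = config.supine1_s
    b2 = b1 + t1
    b3 = b2 + config.trendelenburg_s
    b4 = b3 + t2
    b5 = b4 + config.supine2_s
    sections = [
        ("supine1", b0, b1),
        ("transition", b1, b2),
        ("trendelenburg", b2, b3),
        ("transition", b3, b4),
        ("supine2", b4, b5),
    ]
    duration = b5

    subj_amp, subj_width, subj_hr = _subject_physiology(rng, config)
    onsets, periods = _beat_schedule(rng, duration, config, subj_hr)
    slow_a, slow_w, jitter_a, phi_d = _beat_modulation(rng, onsets, config)
    in_trend = (onsets >= b2) & (onsets < b3)

    dc_sup = config.dc_levels["supine"]
    dc_tre = config.dc_levels["trendelenburg"]
    knots_t = [b0, b1, b2, b3, b4, b5]
    knots_v = [dc_sup, dc_sup, dc_tre, dc_tre, dc_sup, dc_sup]

    n = int(round(duration * config.sample_rate_hz))
    t = np.arange(n) / config.sample_rate_hz
    dc_cond = np.interp(t, knots_t, knots_v)
    drift = 1.0 + config.dc_drift * np.sin(2 * np.pi * t / 137.0 + phi_d)
    dc_beat = np.interp(onsets, knots_t, knots_v)
    noise_scale = config.noise_sd * config.pulse_fraction * dc_sup
    morph = config.morphology

    samples: dict[str, np.ndarray] = {}
    for det in ("distal", "proximal"):
        mult = _detector_multipliers(config, det)
        amp_cond = np.where(in_trend, mult.get("amplitude", 1.0), 1.0)
        width_cond = np.where(in_trend, mult.get("width", 1.0), 1.0)
        amps = config.pulse_fraction * dc_beat * subj_amp * amp_cond * slow_a * jitter_a
        widths = morph.width * subj_width * width_cond * slow_w
        pulse = _render_pulse_train(t, onsets, periods, amps, widths, morph)
        for wl in config.wavelengths:
            noise = noise_scale * rng.standard_normal(n) if config.noise_sd > 0 else 0.0
            samples[Channel(det, wl).name] = dc_cond * drift + pulse + noise

    peaks = onsets + morph.rise_fraction * periods
    peaks = peaks[peaks < duration]
    return _assemble(config, subject_id, samples, sections, peaks)


def generate_valsalva_recording(config: SynthConfig, subject_id: str):
    """Simulate one subject's Valsalva-protocol recording.

    A seated baseline is followed by ``n_valsalva`` strain windows.  During a
    strain the DC level ramps up by ``valsalva_dc_ramp`` with fast
    (``valsalva_ramp_s``) onset and release edges — the transients that the
    derivative-envelope sectioning keys on — and the distal pulse morphology
    is transiently scaled by the condition effects (attenuated proximally).
    """
    if config.protocol != "valsalva":
        raise ValueError("config.protocol must be 'valsalva' for a valsalva recording")
    rng = np.random.default_rng([int(config.seed), _subject_key(subject_id)])

    starts = [
        config.baseline_s + i * (config.valsalva_s + config.recovery_s)
        for i in range(config.n_valsalva)
    ]
    windows = [(s, s + config.valsalva_s) for s in starts]
    for (s0, e0), (s1, _) in zip(windows, windows[1:]):
        if e0 + config.valsalva_ramp_s >= s1:
            raise ValueError("valsalva windows would overlap given configured durations")
    duration = windows[-1][1] + config.tail_s
    sections = [("baseline", 0.0, config.baseline_s)] + [
        (f"valsalva{i + 1}", s, e) for i, (s, e) in enumerate(windows)
    ]

    subj_amp, subj_width, subj_hr = _subject_physiology(rng, config)
    onsets, periods = _beat_schedule(rng, duration, config, subj_hr)
    slow_a, slow_w, jitter_a, phi_d = _beat_modulation(rng, onsets, config)

    n = int(round(duration * config.sample_rate_hz))
    t = np.arange(n) / config.sample_rate_hz

    def effect_profile(x: np.ndarray) -> np.ndarray:
        e = np.zeros_like(x)
        for s, eend in windows:
            e += _smoothstep(x, s, config.valsalva_ramp_s) - _smoothstep(
                x, eend, config.valsalva_ramp_s
            )
        return np.clip(e, 0.0, 1.0)

    e_t = effect_profile(t)
    e_beat = effect_profile(onsets)
    dc_base = config.dc_levels.get("baseline", 5.0)
    dc_cond = dc_base * (1.0 + config.valsalva_dc_ramp * e_t)
    drift = 1.0 + config.dc_drift * np.sin(2 * np.pi * t / 137.0 + phi_d)
    dc_beat = dc_base * (1.0 + config.valsalva_dc_ramp * e_beat)
    noise_scale = config.noise_sd * config.pulse_fraction * dc_base
    morph = config.morphology

    samples: dict[str, np.ndarray] = {}
    for det in ("distal", "proximal"):
        mult = _detector_multipliers(config, det)
        amp_cond = 1.0 + (mult.get("amplitude", 1.0) - 1.0) * e_beat
        width_cond = 1.0 + (mult.get("width", 1.0) - 1.0) * e_beat
        amps = config.pulse_fraction * dc_beat * subj_amp * amp_cond * slow_a * jitter_a
        widths = morph.width * subj_width * width_cond * slow_w
        pulse = _render_pulse_train(t, onsets, periods, amps, widths, morph)
        for wl in config.wavelengths:
            noise = noise_scale * rng.standard_normal(n) if config.noise_sd > 0 else 0.0
            samples[Channel(det, wl).name] = dc_cond * drift + pulse + noise

    peaks = onsets + morph.rise_fraction * periods
    peaks = peaks[peaks < duration]
    return _assemble(config, subject_id, samples, sections, peaks)


def generate_recording(config: SynthConfig, subject_id: str):
    """Dispatch on ``config.protocol``."""
    if config.protocol == "tilting":
        return generate_tilting_recording(config, subject_id)
    return generate_valsalva_recording(config, subject_id)


def null_config(config: SynthConfig) -> SynthConfig:
    """A copy of ``config`` with all condition effects switched off."""
    return replace(
        config,
        condition_effects={k: 1.0 for k in config.condition_effects},
        valsalva_dc_ramp=0.0,
        dc_levels={k: config.dc_levels.get("supine", 5.0) for k in config.dc_levels},
    )
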