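# nirpulse

Pulse-morphology analysis of forehead near-infrared optical signals under
induced intracranial-pressure (ICP) changes.

## The problem

ICP is monitored invasively in neurocritical care. A candidate non-invasive
alternative is a forehead reflectance probe with near-infrared emitters and
two photodiodes: a *proximal* detector (10 mm from the source, extracerebral
tissue) and a *distal* detector (35 mm, deeper cerebral tissue). The
slowly-varying (DC) part of the backscattered light is classical
near-infrared spectroscopy; this package analyses the *pulsatile* (AC)
component instead — the photoplethysmographic (PPG) waveform — whose
morphology responds to intracranial volume, and hence pressure, changes
induced by head-down (Trendelenburg −30°) tilting and Valsalva maneuvers.
Because only the distal detector reaches cerebral tissue, condition effects
should be stronger on the distal channel: that asymmetry is the signature of
a brain-derived signal.

`nirpulse` is a library (no CLI); its importable API covers the full chain,
with `examples/` giving one narrative script per capability:

1. **synthetic data** (`nirpulse.synth`) — seeded, ground-truth-annotated
   two-channel recordings for both protocols (volunteer recordings for this
   kind of study are typically not deposited);
2. **preprocessing** (`nirpulse.preprocess`) — undersampling to 100 Hz,
   zero-phase 2nd-order Butterworth filters (AC: 0.8–10 Hz band-pass, DC:
   0.1 Hz low-pass), and the normalized signal `ac/dc × 10`;
3. **sectioning** (`nirpulse.sectioning`) — tilting by time (average
   transition recovered from record length; middle 60% of each position
   kept) and Valsalva from the Savitzky–Golay-smoothed first-derivative
   envelope, with boundaries snapped to first/second-derivative crossings;
4. **features** (`nirpulse.features`) — per-beat morphology
   F1 amplitude, F2 half-height width, F3 upslope (F1/F5), F4 decay time,
   F5 rise time, F6 area, F7 systolic area, F8 diastolic area, F9 = F7/F8,
   aggregated as windowed medians (15 s tilting / 5 s Valsalva);
5. **statistics** (`nirpulse.stats`) — Shapiro–Wilk / Kolmogorov–Smirnov /
   Bartlett assumption checks, Mann–Whitney U and Kruskal–Wallis contrasts,
   Box–Cox transformation with maximum-likelihood λ, and a two-factor
   (condition × detector) linear model with interaction, Type II sums of
   squares, at α = 0.05;
6. **classification** (`nirpulse.classify`) — 810 nm distal rows only,
   per-subject random undersampling to balance classes, min–max scaling,
   ridge-stabilized logistic regression under leave-one-subject-out (LOSO)
   and shuffled row-level 10-fold cross-validation, reporting sensitivity,
   specificity and accuracy per fold;
7. **pipeline** (`nirpulse.pipeline`) — the orchestrated, manifest-driven
   end-to-end run, reproducible byte for byte.

## Worked example

```python
from nirpulse import (SynthConfig, generate_tilting_recording,
                      preprocess_recording, prepare_dataset, loso_validate)
from nirpulse.features import SectionedChannel, build_feature_table
from nirpulse.sectioning import section_tilting

items = []
cfg = SynthConfig(seed=5)                      # 70 bpm, distal effects x1.3 amp / x1.15 width
for i in range(8):
    rec, _ = generate_tilting_recording(cfg, f"s{i+1:02d}")
    dec = preprocess_recording(rec)            # 100 Hz AC/DC/normalized per channel
    sections = section_tilting(len(dec["distal_810"].normalized), 100.0)
    for det in ("distal", "proximal"):
        items.append(SectionedChannel(f"s{i+1:02d}", "tilting", det, 810,
                                      dec[f"{det}_810"].normalized, 100.0, sections))
table = build_feature_table(items, edge_guard_s=3.75)
for det in ("distal", "proximal"):
    report = loso_validate(prepare_dataset(table, "tilting", seed=1, detector=det))
    print(det, round(report.mean_sensitivity, 1), round(report.mean_specificity, 1))
```

prints (`examples/06_classification.py`):

```
distal: 186 balanced rows, 8 subjects
  leave-one-subject-out: sensitivity 97.9% specificity 86.7% accuracy 92.3%
proximal: 186 balanced rows, 8 subjects
  leave-one-subject-out: sensitivity 62.3% specificity 63.5% accuracy 62.9%
```

The distal channel classifies Trendelenburg vs supine well above chance and
well above the proximal channel — the generator puts the condition signal in
the deep channel, and the pipeline recovers that ordering. Row-level 10-fold
validation scores higher than LOSO because subject structure leaks across
folds; both schemes are reported side by side for that reason.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full analysis from scratch on synthetic cohorts of both
protocols — generation, decomposition, sectioning, feature extraction, the
statistical battery and both validation schemes — prints a per-protocol
summary, and writes the report JSON to `--out`.

See `docs/methods.md` for the model, parameter defaults, numerical choices
and known limitations.
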