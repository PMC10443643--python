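"""Section both protocols into labeled condition segments.

Tilting is sectioned by time: the average transition duration is recovered
from the record length and the middle 60% of each position window is kept.
Valsalva maneuvers are found from the signal itself via the smoothed
first-derivative envelope: strain onsets spike the upper envelope, releases
the lower envelope, and boundaries snap to first/second-derivative crossings.
"""

from nirpulse import (
    SynthConfig,
    generate_tilting_recording,
    generate_valsalva_recording,
    preprocess_recording,
    section_tilting,
    section_valsalva,
)

# -- tilting: metadata-driven -------------------------------------------------
rec, _ = generate_tilting_recording(SynthConfig(seed=1), "s01")
norm = preprocess_recording(rec)["distal_810"].normalized
print("tilting sections (middle 60% of each position window):")
for s in section_tilting(len(norm), 100.0):
    print(f"  {s.label:<14} [{s.start_s(100.0):7.1f}, {s.end_s(100.0):7.1f}) s")

# -- valsalva: signal-driven --------------------------------------------------
rec, truth = generate_valsalva_recording(SynthConfig(seed=1, protocol="valsalva"), "v01")
norm = preprocess_recording(rec)["distal_810"].normalized
print("\nvalsalva sections (detected from the derivative envelope):")
for s in section_valsalva(norm, 100.0):
    print(f"  {s.label:<10} [{s.start_s(100.0):6.1f}, {s.end_s(100.0):6.1f}) s")
print("true maneuver windows:")
for label, start, end in truth.true_sections:
    if label.startswith("valsalva"):
        print(f"  {label:<10} [{start:6.1f}, {end:6.1f}) s")
# Detected windows should overlap the true windows almost exactly; the
# baseline segment has the mean maneuver duration and ends 5 s before the
# first strain.
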