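"""Generate a synthetic two-channel forehead recording for the tilting protocol.

The tilting protocol raises intracranial pressure by head-down (Trendelenburg,
-30 degrees) positioning: supine 5 min -> Trendelenburg 5 min -> supine 2 min,
with 30-60 s transitions.  The distal photodetector (deep, cerebral tissue)
carries stronger condition effects than the proximal one.
"""

import numpy as np

from nirpulse import SynthConfig, generate_tilting_recording

config = SynthConfig(seed=1)
recording, truth = generate_tilting_recording(config, subject_id="s01")

print(f"recording: {recording.duration_s:.1f} s at {recording.sample_rate_hz:.0f} Hz, "
      f"channels {sorted(recording.samples)}")
print("protocol ground truth:")
for label, start, end in truth.true_sections:
    print(f"  {label:<14} {start:7.1f} - {end:7.1f} s")
beats = truth.beat_times["distal"]
print(f"{len(beats)} systolic peaks; mean heart rate "
      f"{60.0 / np.mean(np.diff(beats)):.1f} bpm")
print("distal condition multipliers:", truth.applied_multipliers["distal"])
print("proximal (attenuated):       ", truth.applied_multipliers["proximal"])
# The proximal multipliers sit 30% of the way from 1.0 to the distal values:
# only the distal detector interrogates cerebral tissue.
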