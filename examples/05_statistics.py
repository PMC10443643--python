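"""Run the statistical battery over a small synthetic cohort.

Per feature: Mann-Whitney U (supine vs Trendelenburg, per detector) and a
two-factor linear model (condition x detector with interaction, Type II sums
of squares) on a Box-Cox-transformed response when the normality or
variance-homogeneity assumptions fail.
"""

from nirpulse import SynthConfig, generate_tilting_recording, preprocess_recording
from nirpulse.features import SectionedChannel, build_feature_table
from nirpulse.preprocess import EDGE_GUARD_S
from nirpulse.sectioning import section_tilting
from nirpulse.stats import feature_statistics

items = []
cfg = SynthConfig(seed=3)
for i in range(4):
    sid = f"s{i + 1:02d}"
    rec, _ = generate_tilting_recording(cfg, sid)
    decomp = preprocess_recording(rec)
    sections = section_tilting(len(decomp["distal_810"].normalized), 100.0)
    for det in ("distal", "proximal"):
        items.append(SectionedChannel(sid, "tilting", det, 810,
                                      decomp[f"{det}_810"].normalized, 100.0, sections))
table = build_feature_table(items, edge_guard_s=EDGE_GUARD_S)
results = feature_statistics(table, "tilting")

print(f"{len(table)} feature rows from 4 subjects")
mw = results[results.test == "mann-whitney-u"]
print("\nMann-Whitney supine vs Trendelenburg (p-values):")
print(mw.pivot(index="feature", columns="contrast", values="p_value").round(4).to_string())
anova = results[results.test == "factorial-anova"]
sig = anova.groupby("contrast")["significant"].mean()
print("\nfactorial model: fraction of features significant per term:")
print(sig.to_string())
# Amplitude/width/area features should show small p-values (the generator
# injects a distal amplitude x1.3 and width x1.15 effect); the detector term
# reflects the distal-vs-proximal attenuation.
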