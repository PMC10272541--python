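"""Generate one synthetic SHG/TPEF liver sample with ground truth.

The generator paints dark fat vacuoles of two size classes into a bright
TPEF tissue field and bright collagen strings into a dark SHG field, and
records every object it placed.
"""

from shgquant import SyntheticSpec, generate_sample

spec = SyntheticSpec(
    target_steatosis_area_pct=20.0,  # aim for grade-1 steatosis
    macro_fraction=0.7,              # 70% of the fat area is macrovesicular
    fibrosis_stage=2,                # designed NASH CRN stage
    collagen_coupling=0.6,           # 60% of strings placed near macro vacuoles
    noise_sd=8.0,
    seed=1,
)
sample = generate_sample(spec)
truth = sample.truth

print(f"canvas: {sample.shg.shape} px at {sample.pixel_size_um:.6f} um/px")
print(f"realized steatosis area: {truth.true_area_pct:.2f}% "
      f"(macro {truth.true_macro_area_pct:.2f}% + micro {truth.true_micro_area_pct:.2f}%)")
print(f"NASH CRN steatosis grade from that area: {truth.steatosis_grade}")
print(f"vacuoles placed: {len(truth.vacuole_records)}; "
      f"collagen strings placed: {len(truth.string_records)}")
coupled = sum(r.coupled for r in truth.string_records)
print(f"strings within the co-localization distance of a macro vacuole: {coupled}")
# The realized area tracks the requested target to within the size of the
# smallest vacuole; the grade is derived from the realized area, so the
# ground truth is always self-consistent.
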