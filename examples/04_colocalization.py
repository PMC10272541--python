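"""Restrict fibrosis quantification to collagen near each steatosis class.

The neighbourhood of a class is its vacuole mask dilated by a fixed
distance (default 10 um) intersected with the perisinusoidal region.  Two
cohorts differing only in the generator's collagen_coupling show how the
co-localized fraction separates coupled from uncoupled collagen.
"""

import dataclasses
import numpy as np

from shgquant import SyntheticSpec, generate_cohort
from shgquant.pipeline import quantify_sample

base = SyntheticSpec(target_steatosis_area_pct=12.0, macro_fraction=0.7,
                     fibrosis_stage=2, noise_sd=0.0, shape=(384, 384))

for coupling in (1.0, 0.0):
    design = [("demo", 0, dataclasses.replace(base, collagen_coupling=coupling)) for _ in range(3)]
    samples, _ = generate_cohort(design, seed=4)
    rows = [quantify_sample(s) for s in samples]
    frac = np.mean([r["ColocFracMacro"] for r in rows])
    near = np.mean([r["#ThinStrPS-MacroCoLoc"] for r in rows])
    total = np.mean([r["#ThinStrPS"] for r in rows])
    print(f"coupling={coupling:.0f}: collagen fraction near macrosteatosis = {frac:.3f}  "
          f"(#ThinStrPS near macro: {near:.1f} of {total:.1f})")
# With coupling 1 nearly all perisinusoidal collagen sits within 10 um of a
# macro vacuole; with coupling 0 almost none does.  Co-localized counts can
# never exceed their unrestricted counterparts.
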