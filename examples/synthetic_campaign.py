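"""Generate a synthetic wet-lab campaign and analyse it end to end.

Emulates the measurement campaign the analysis pipeline expects: noisy
triplicate swelling series, caliper dimensions, a 25-day degradation
series, a cyclic pH-switch series, and colorimetric assay readouts.
"""

import numpy as np

from cugel import (SyntheticConfig, cyclic_reversibility,
                   dimensional_variation, fit_degradation, gen_caliper_series,
                   gen_cyclic_series, gen_degradation_series, gen_mass_series,
                   invert_calibration, swelling_ratio)
from cugel.synthetic import gen_assay_readout

cfg = SyntheticConfig(seed=42)

# Noisy triplicates: ratio mean +/- SD, as a bench notebook would report it.
for material in ("paam", "chitosan"):
    reps = gen_mass_series(material, "7", cfg)
    ratios = [swelling_ratio(s.masses[0], s.masses[-1]) for s in reps]
    print(f"{material:<9} 24-h swelling ratio = "
          f"{np.mean(ratios):+.0f}% +/- {np.std(ratios, ddof=1):.0f}%  (n=3)")

# Caliper dimensions reproduce the anisotropic deformation targets.
(d4, d7) = gen_caliper_series("chitosan", cfg)[0]
dc = dimensional_variation(d4, d7)
print(f"chitosan deformation: axial {dc.axial_percent:+.1f}%, "
      f"radial {dc.radial_percent:+.1f}%")

# Degradation: chitosan loses mass and plateaus near day 10.
summary = fit_degradation(gen_degradation_series("chitosan", cfg))
print(f"chitosan degradation plateau near day {summary.plateau_day:.1f}")

# Cyclic pH switching is reversible by default.
drift = cyclic_reversibility(gen_cyclic_series("paam", cfg))
print(f"cyclic same-pH drift = {drift:.2g}%")

# Colorimetric assay: absorbances invert back to concentration.
true_conc = 2.7e-5
readings = gen_assay_readout(true_conc, cfg, n=3)
est = invert_calibration(readings, cfg)
print(f"assay: true {true_conc:.2e} M -> measured {est.mean():.2e} M")
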