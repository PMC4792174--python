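"""Calibrate body-water deuterium enrichment from GC-MS measurements.

Simulates an 11-point acetone-exchange standard curve (0-20% molar 2H2O),
converts sample ion-intensity ratios to molar enrichments, and fits the
first-order enrichment curve p(t) = p_ss (1 - e^(-k_p t)).
"""

import numpy as np

from turnoverkit import (
    EnrichmentCurve,
    enrichment_from_ratio,
    fit_enrichment_curve,
    fit_standard_curve,
)

rng = np.random.default_rng(7)

# standard curve: known molar fractions vs measured m/z 59/58 ratios
fractions = np.linspace(0.0, 0.20, 11)
true_slope = 0.47  # instrument response: fraction per unit intensity ratio
ratios = fractions / true_slope + rng.normal(0, 0.001, 11)
curve = fit_standard_curve(fractions, ratios)
print(f"standard curve: fraction = {curve.slope:.4f} * ratio + {curve.intercept:.5f}")

# mouse plasma samples: 2 animals per day over the labeling course
days = np.repeat([0.0, 1.0, 3.0, 5.0, 7.0, 10.0, 14.0], 2)
truth = EnrichmentCurve(p_ss=0.045, k_p=2.0)
sample_ratios = (truth.p_at(days) + rng.normal(0, 0.002, len(days))) / curve.slope
enrichments = [enrichment_from_ratio(curve, r) for r in sample_ratios]

fit = fit_enrichment_curve(days, enrichments)
print(f"fitted p_ss = {fit.p_ss:.4f} (true 0.045), k_p = {fit.k_p:.2f}/d (true 2.0)")
print("(p_ss is the plateau body-water enrichment; k_p sets how fast the pool")
print(" equilibrates -- the kinetic model uses both to correct early time points.)")
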