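"""Pre-screen noninvasive samples with qPCR before library prep.

Fits a standard curve from a 10-fold dilution series, quantifies unknowns
from their Cq values, then fits the logistic model of genotyping success
vs host-DNA concentration and inverts it: how much DNA is needed for a
95% chance of genotyping at least half the panel?
"""

from gtpanel import qpcr, synth

points = synth.simulate_standard_curve_points(intercept=22.0, slope=-3.32)
curve = qpcr.fit_standard_curve(points)
print(f"standard curve: Cq = {curve.intercept:.2f} {curve.slope:+.2f}*log10(conc), "
      f"efficiency {100 * curve.efficiency:.1f}%")
print(f"a Cq of 25.3 quantifies to {qpcr.quantify(25.3, curve):.3f} ng/uL")

cfg = synth.SimConfig(seed=19, logistic_params=(-2.0, 6.0))
data = synth.simulate_screen_data(cfg, n_samples=300)
model = qpcr.fit_screen_model(data, success_threshold=0.5)
thr = qpcr.concentration_for_probability(model, 0.95)
print(f"screen model: logit P(>=50% loci) = {model.intercept:.2f} "
      f"+ {model.slope:.2f}*conc  (n={model.n_obs})")
print(f"concentration for 95% success probability: {thr:.2f} ng/uL")
# Samples below the threshold are unlikely to return usable genotypes and
# can be excluded before spending sequencing budget.
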