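"""Product-inhibition pattern of NADH versus NAD+.

Simulates initial rates at four NADH levels (17-220 uM) with SSA
saturating and NAD+ varied, fits a double-reciprocal line per level, and
classifies the pattern from where the lines intersect.  Lines converging
on the y-axis are the competitive signature — NADH and NAD+ contend for
the same (free-enzyme) form, as expected for an ordered mechanism with
NAD+ binding first.  K_i comes from the slope replot.
"""

from ssadhkin import OrderedBiBiParams, product_inhibition_analysis
from ssadhkin.synthetic import NoiseModel, gen_product_inhibition

truth = OrderedBiBiParams(vmax=166, k_a=84, k_b=4, k_ia=84)
data = gen_product_inhibition(truth, ki_nadh_um=30.0,
                              noise=NoiseModel(cv=0.03, seed=8))
res = product_inhibition_analysis(data)
print(f"pattern: {res.pattern}")
print(f"Ki(NADH) = {res.ki_um:.1f} uM (true 30)")
print(f"mean intersection abscissa: {res.convergence_point[0]:.2e} "
      "(1/uM; ~0 = on the y-axis)")
for i_conc, m, c in zip(res.inhibitor_um, res.slopes, res.intercepts):
    print(f"  [NADH] {i_conc:>5.0f} uM: slope {m:.3f}, intercept {c:.4f}")
print("Slopes rise with [NADH] while intercepts stay put: competitive.")
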