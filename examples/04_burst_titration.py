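"""Stopped-flow burst kinetics and active-site titration.

Simulates NADH-formation traces at five enzyme concentrations (4-14 uM
active sites), fits the burst model offset + A(1-exp(-lambda t)) + v t
to each, and regresses the burst amplitude on enzyme concentration.  A
titration slope near 1 means every active site completes the first
turnover (hydride transfer outruns the steps after it).
"""

from ssadhkin import active_site_titration, fit_burst
from ssadhkin.synthetic import NoiseModel, gen_burst_traces

traces = gen_burst_traces(
    amplitude_per_site=1.0, lambda_per_s=150.0, steady_rate_per_site=2.0,
    noise=NoiseModel(kind="additive_gaussian", sigma_add=0.002, seed=6))
fits = [fit_burst(tr) for tr in traces]
print(f"{'[E] (uM)':>9}{'burst (uM)':>12}{'lambda (1/s)':>14}")
for f in fits:
    print(f"{f.enzyme_um:>9.0f}{f.amplitude_um:>12.2f}"
          f"{f.lambda_per_s:>14.0f}")
line = active_site_titration(fits)
print(f"titration: slope = {line.slope:.3f} NADH per site "
      f"(r^2 = {line.r2:.4f})")
print("slope ~1: all active sites are catalytically competent; the burst"
      " completes within ~20 ms at lambda ~150 s^-1.")
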