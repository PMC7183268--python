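"""Fit glucose-uptake kinetics and compare shape classes.

Bulk glucose depletes as it diffuses into hollow capsules; the bulk
concentration follows C(t) = c_eq + (c0 - c_eq)·exp(-k·t).  Deformed
capsules have locally thin walls and take up glucose faster.
"""

import numpy as np

from capsize.permeation import compare_permeation, dns_calibrate, fit_uptake, initial_rate
from capsize.synthetic import gen_uptake_series

# DNS assay standard curve: absorbance at 540 nm vs known glucose (mg/mL)
standards = [(0.05, 1.0), (0.21, 4.0), (0.52, 10.0), (1.05, 20.0)]
curve = dns_calibrate(standards)
print(f"standard curve: C = {curve.slope:.2f}·A + {curve.intercept:.2f} "
      f"(R² = {curve.r_squared:.4f})")

times = np.arange(0.0, 7501.0, 300.0)
fits = {}
for cls, k_true in (("spherical", 5.0e-4), ("deformed", 1.5e-3)):
    series = gen_uptake_series(20.0, 16.8, k_true, times, sigma=0.01, rng=3)
    fit = fit_uptake(series)
    fits[cls] = fit
    print(f"{cls:9s}: k = {fit.k:.2e} /s, half-time = {fit.half_time:6.0f} s, "
          f"initial rate = {initial_rate(series):+.2e} mg/mL/s")

cmp_ = compare_permeation([fits["spherical"]], [fits["deformed"]])
print(f"\nordering: {cmp_.ordering}")
# The deformed class equilibrates ~3x faster - uneven walls make release
# rates hard to control, which is why spherical capsules are preferred for
# sustained-release formulations.
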