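"""Score capsule sphericity and reproduce the shape-vs-viscosity curves.

Uses the bundled measured condition grids: batch-mean sphericity factor
(SF) and diameter D on a (core viscosity × bath viscosity) grid.
"""

from capsize import datasets
from capsize.core import round_half_up
from capsize.shape import (
    GridAxis,
    classify,
    grid_average,
    percent_change,
    sphericity_factor,
    threshold_crossing,
)

# One capsule measured with calipers: longest axis 4.4 mm, shortest 4.0 mm.
sf = sphericity_factor(4.4, 4.0)
print(f"single capsule: SF = {sf:.4f} -> {classify(sf).value}")
# SF < 0.07 means the two axes differ by < ~15%, i.e. visually spherical.

# Average the measured SF grid over core viscosities: how does the gelation
# bath's viscosity distort capsule shape?
sf_curve = grid_average(datasets.sphericity_grid(), GridAxis.OVER_CORE_VISCOSITY)
print("\nmean SF vs bath (SA) viscosity:")
for x, m, n in zip(sf_curve.x, sf_curve.mean, sf_curve.n):
    print(f"  {x:7.1f} mPa·s  SF = {m:.3f}  (n = {n} formed conditions)")

crossing = threshold_crossing(sf_curve, 0.07)
print(f"capsules stay spherical below ~{crossing:.2f} mPa·s bath viscosity")

d_curve = grid_average(datasets.diameter_grid(), GridAxis.OVER_CORE_VISCOSITY)
drop = percent_change(d_curve.mean[0], d_curve.mean[-1])
print(
    f"\nmean D falls {round_half_up(drop, 1)}% "
    f"({round_half_up(d_curve.mean[0])} -> {round_half_up(d_curve.mean[-1])} mm) "
    "across the same viscosity range"
)
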