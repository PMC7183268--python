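# Methods

## Scope and units

`capsize` analyzes bench measurements of millimeter-scale calcium-alginate
capsules: caliper diameter pairs, solution property tables, force–
displacement compression records and glucose-uptake time series.  The
public API uses bench units throughout (mm, mN/m, mPa·s, kg/m³, N, mg/mL,
wt.% or g/L); every physics formula converts to SI internally and converts
back, so calling code never handles unit factors.  Report output rounds
half-up to 3 decimals for mm and SF values, matching how such tables are
printed.

## Sphericity and shape classification

SF = (D_max − D_min)/(D_max + D_min), with the capsule diameter D defined
as D_min (the short axis is what calipers and micrometers measure
reproducibly on a teardrop).  Classification uses a strict SF < 0.07
threshold; a value exactly at the threshold is deformed.  Batch statistics
use the arithmetic mean and the n−1 sample SD; the dispersion columns of
measured grids are treated as SDs.  Grid aggregation skips "no capsule
formed" cells (empty in CSV, NaN in memory — never 0) and reports the
effective n per point; an all-missing axis value is dropped with a
warning, not zeroed.

The viscosity limit for spherical capsules is found by piecewise-linear
interpolation of the aggregated mean-SF curve at 0.07.  On the bundled
measured grid this gives ≈ 52.98 mPa·s; a slightly different figure can be
obtained by fitting a smooth curve first, and the package deliberately does
not do that — the interpolation rule is simple, assumption-free and
documented, and the curve's own sampling (five viscosities) does not
support a more elaborate estimate.

## Modified Tate's law

Tate's balance m·g = π·d_t·γ gives the detached-drop volume, hence a drop
diameter (6·d_t·γ/(ρ·g))^(1/3).  Two empirical factors correct it:
K_LF = 0.98 − 0.04·d_t (d_t in mm; 0.9376 for the 1.06 mm 19G needle used
as default) for the liquid that stays at the nozzle, and K_SF = D/d_d for
the size change during gelation.  The composition is multiplicative,
K = K_LF·K_SF — both factors are diameter ratios, so any other composition
would be dimensionally arbitrary.  K_SF is pooled across calibration pairs
by arithmetic mean; per-condition factors are exposed separately
(`per_condition_factors`) for circular per-condition checks.

K_LF is interpreted as a *diameter* correction: the detached mass is
K_LF³·π·d_t·γ/g, so that a drop weighed at the nozzle, converted to d_d by
the sphere formula, equals K_LF·(6·d_t·γ/(ρ·g))^(1/3).  This is the only
reading under which a noiseless calibrate→predict→validate round trip
closes exactly (AAD = MAD = 0), and the synthetic generator uses it.

AAD = mean(|d_p − D|/d_p)·100 and MAD = max of the same per-pair
percentages; the denominator is the *predicted* diameter.  Under pure
multiplicative observation noise of SD σ the per-pair deviation is
approximately half-normal, so E[AAD] ≈ σ·√(2/π)·100 (≈ 1.6% at σ = 0.02);
the test suite checks this to 3 standard errors.

## Shell mechanics

The small-deformation response of a thin-walled liquid-filled sphere under
point/plate load is the Reissner relation

    F = 4·E_s·h·d_D / (r·√(3·(1 − ν_s²)))

with E_s the surface Young's modulus (N/m, i.e. modulus × thickness), h the
membrane thickness (fixed default 0.20 mm), r the capsule radius and ν_s
the surface Poisson ratio (default 1/2 for alginate hydrogel, which makes
the geometric factor exactly 3/2).  The printed form of this relation in
compression-testing literature is often typeset ambiguously; the form above
is the one that is dimensionally consistent with E_s in N/m, and the whole
inversion is linear, so any alternative constant prefactor would rescale
E_s uniformly without affecting class *ratios*.

The fit is least-squares on the 0–1 mm window, through the origin by
default (a capsule exerts no force before plate contact; a free-intercept
fit is available via `through_origin=False`).  A negative fitted slope
clamps E_s to 0 with a warning.  R² for the through-origin fit uses the
uncentered total sum of squares, the standard definition for no-intercept
regression.

Crushing detection is an implementation-defined rule (raw rupture curves
are instrument-specific): track the running force maximum; the first time
the force falls at least `drop_fraction` (default 20%) below that maximum
within `lookahead` (default 3) samples of it, the maximum is the crushing
point.  Monotone non-decreasing curves never fire, and the rule is
invariant to uniform force rescaling.  Both knobs are configurable.

## Permeation kinetics

Glucose uptake is modelled as first-order exchange between a well-mixed
bulk and a population of identical membrane-limited capsules:
C(t) = c_eq + (c0 − c_eq)·e^(−kt) for the bulk concentration.  This is the
simplest model consistent with a saturating depletion curve; it ignores
intra-capsule gradients and capsule-to-capsule variability.  Fitting is
bounded nonlinear least squares (c0, c_eq, k ≥ 0) with initial guesses
from the series endpoints and a log-linear slope; a constant series is the
k = 0 degenerate case and short-circuits the fitter.  Derived quantities:
half-time ln2/k and initial rate −k(c0 − c_eq).  The DNS standard curve
(concentration vs 540 nm absorbance) is an ordinary least-squares line.
The default equilibrium level in the generator, c_eq = 16.8 mg/mL from
c0 = 20 mg/mL, is the volume balance of 100 mL bulk against ~19 mL of
internal volume in 500 four-mm capsules.

## Synthetic study generator

The generator reproduces the statistical structure of the bench study so
that parameter-recovery tests are meaningful:

* **Viscosity–concentration**: a·exp(b·c) anchored exactly at the measured
  endpoints (SA: 0.25 wt.% → 16.2 mPa·s, 1.25 wt.% → 516.0 mPa·s;
  CaCl₂/CMC: 0.5 → 20.0, 1.5 → 917.5).  Densities fixed at 1055 / 1065
  kg/m³.
* **Surface tension**: Tween 80 in CaCl₂/CMC follows a log-linear decay
  through (0.015 g/L, 49.01 mN/m) and (0.075, 37.0) with a flat plateau at
  37 mN/m above 0.075 g/L — the critical-micelle signature — and 63.41
  mN/m at zero dose.  Poloxamer 407 in SA decays exponentially from 47.01
  mN/m toward a 37 mN/m asymptote, anchored at (0.1 wt.%, 41.71); block
  copolymers aggregate over a dose range, so the curve has no sharp break.
* **Droplets**: masses K_LF³·π·d_t·γ/g with 1% multiplicative noise (real
  drop-mass variability is unreported; 1% is a placeholder consistent with
  gravimetric dosing).
* **Capsules**: d_min = true_D·(1+ε₁), and SF inverted exactly through
  d_max = d_min·(1+s)/(1−s) with s = true_SF·(1+ε₂); ε ~ N(0, 0.02).  The
  2% multiplicative diameter noise matches the 1–4% SD/mean dispersion of
  the measured batches (n = 15 per condition).  The default study design
  takes its per-condition true SF and D from the bundled measured grids,
  so synthetic studies inherit the real shape/size trends, including the
  unformed low-core-viscosity row.
* **Force curves**: exact Reissner line to 1 mm, a slope-continuous
  quadratic stiffening to the rupture point (default 18.1 N at 3.96 mm for
  the spherical class), then an exponential post-rupture collapse to 50%;
  2% force noise.  Deformed-class curves get no rupture event, emulating
  capsules that fail below the detection limit.
* **Uptake**: the first-order model forward-simulated with 1% noise;
  deformed capsules get k = 1.5×10⁻³ s⁻¹ vs 5×10⁻⁴ s⁻¹ spherical (a ~3×
  contrast).

All draws flow from a single seeded `numpy.random.Generator` per
`gen_study` call; identical seed and design give byte-identical CSVs
(writers emit shortest-round-trip float reprs and readers parse with
round-trip precision).

What the generator does *not* emulate: droplet impact hydrodynamics and
penetration depth (the physical cause of deformation — the generator takes
per-condition SF as given), gelation kinetics, membrane thickness
variation within a capsule, instrument drift, and non-Gaussian outliers.
Passing recovery tests therefore demonstrate that the estimators are
correct and well-conditioned under realistic dispersion, not that the
underlying physical models are exhaustive.

## Validation experiment sizes

The headline validation (and `scripts/acceptance.py`) uses 500
capsule-condition draws with surface tensions uniform on 36–64 mN/m (the
span reachable by surfactant dosing), density 1065 kg/m³, 1% mass noise
and 2% diameter noise, with a true gelation factor K_SF = 1.3 (consistent
with a 4.17 mm capsule from a 3.2 mm drop).  At these settings AAD lands
around 1.6–1.8% and MAD around 5–7%.  Mechanics recovery uses 50 noisy
curves; uptake recovery 20 series.  These sizes give Monte-Carlo standard
errors comfortably below the tolerances being checked.

## Numerical notes and edge cases

* Half-up decimal rounding (not banker's) for report tables.
* `threshold_crossing` returns the first crossing and logs when several
  exist; a mean exactly at the level counts as a crossing at that x.
* Ratio tables skip zero-denominator pairs with a warning; an absent
  crushing event cannot enter a ratio.
* Negative forces in a compression record are kept (post-rupture load-cell
  artifacts) but logged; negative concentrations are rejected.
* `fit_uptake` clamps a (noise-induced) fitted c_eq > c0 back to the
  depletion ordering.
* Seeds: every stochastic API takes an integer seed or a
  `numpy.random.Generator`; nothing reads global RNG state.

## Known limitations

* The Reissner inversion assumes small deformations; using it on windows
  beyond ~h·√(r/h) overestimates stiffness.  The 0–1 mm default window is
  appropriate for ~4 mm capsules with 0.2 mm walls.
* Pooling K_SF by arithmetic mean treats gelation shrinkage/swelling as
  condition-independent; per-condition factors are exposed for when it is
  not.
* The permeation model cannot represent biphasic release (e.g. a burst
  from wall defects followed by slow exchange).
* The SF threshold 0.07, crushing drop fraction 0.2 and 3-sample lookahead,
  and the 0–1 mm fit window are conventions, configurable in `RunConfig`.
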