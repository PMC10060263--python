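# Methods

This note records the models, conventions, parameter choices and known
limitations behind `poreflux`. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Data model and conventions

Depths are centimetres below the seafloor, positive downward, taken at the
stated sample depth (no bin midpoints); they are converted to metres inside
the flux mathematics. Concentrations are µM, numerically identical to
mmol m⁻³, so a gradient of 1 µM cm⁻¹ is 100 mmol m⁻⁴. A measurement below
the detection limit is *censored*: the flag is preserved everywhere, and the
stored value is 0 by default (the `half_dl` policy stores DL/2 instead; both
are exposed because the literature uses both). Censored points enter gradient
fits at their stored value. Zonation decisions depend only on flags and
relative comparisons, so all derived zones are invariant under a uniform
positive rescaling of concentrations and detection limits — a property the
suite checks.

Default detection limits are 0.1 µM for nitrate, nitrite and ammonium
(colorimetric flow-analyser methods) and 2 µM for oxygen (optode), all
configurable. When a table lacks a porosity column a constant 0.7 is used and
logged — a typical value for pelagic clay-rich sediments. A site without
stated bottom-water conditions gets T = 2 °C, S = 35, and hydrostatic
pressure from the water depth (1 atm + 1 bar per 10 m): deep-sea bottom-water
typical values.

## Diffusivities

Free-solution diffusion coefficients follow the linear temperature fits
D0 = (m0 + m1·T)·10⁻⁶ cm² s⁻¹ that the porewater-modelling literature uses.
The shipped coefficients are: NO₃⁻ (9.50, 0.388) and NH₄⁺ (9.50, 0.413) —
the standard fits; NO₂⁻ (9.55, 0.390) — the NO₃⁻ fit scaled by the ratio of
limiting equivalent conductivities (71.8 / 71.42 S cm² mol⁻¹), which agrees
with the Nernst–Einstein value at 25 °C to better than 1% (the tests verify
this closed-form anchor independently); O₂ (11.40, 0.446) — a linear
approximation to gas-diffusivity compilations over 0–25 °C, adequate because
no oxygen flux is ever reported (O₂ only enters zonation through its
detection limit). The fits are applied over −2…30 °C; outside that range the
value is extrapolated with a warning.

In-situ correction uses Stokes–Einstein scaling by the dynamic-viscosity
ratio µ(S=0, T, 1 atm)/µ(S, T, P), with the standard empirical seawater
viscosity correlation in salinity, temperature and pressure. At S = 35 the
correction reduces D0 by roughly 5–10%.

The tortuosity correction is Ds = D0/(1 − ln φ²), the form conventionally
paired with this diffusivity table; the Archie-type alternative
Ds = D0·φ^(m−1) is available via `tortuosity="power"` and feeds the
sensitivity report. Because a tortuosity change rescales each solute's Ds by
a near-common factor, the nitrite/nitrate flux ratio is almost insensitive to
the choice, while individual fluxes shift by tens of percent — one reason the
ratio is the more robust cross-site statistic.

## Gradients, fluxes and the ratio

Gradients are ordinary least-squares slopes over exactly three neighbouring
points. With z positive downward, J = φ·Ds·∂[C]/∂z is kept signed internally
(positive = upward transport) and headline quantities are magnitudes with
direction labels, so the result does not depend on a sign convention.

Window anchoring: the nitrate window is the three deepest detectable points
above the depletion crossing; the nitrite windows are the three points at
each end of the coherent interval. The three-point rule does not fully pin
the windows, so `window_anchor="offset1"` (one sample inward) exists as a
sensitivity option, and `compilation_sensitivity` reports the cross-site mean
ratio over the full tortuosity × anchoring grid.

The cross-site summary is the arithmetic mean of per-site ratios with a
Student-t 95% half-width (a bootstrap percentile interval is available);
sites with r ≥ 1 are flagged as outliers rather than dropped.

The discrete net-rate estimator R(zᵢ) = −φ·Ds·C″(zᵢ) uses the three-point
second difference, which is exact for locally quadratic profiles even on
non-uniform grids; endpoints are undefined. Consumption-zone classification
thresholds |R| at 10% (configurable) of the interval's maximum |R|, computed
after dropping the detectable run's edge points, where censoring-to-zero
fabricates curvature. A limb whose curvature never rises above numerical
noise classifies no consumption; a limb with signal but no above-threshold
run falls back to the geometric halves [interval top, maximum] /
[maximum, interval bottom].

## The synthetic generator

The geochemical generator solves 1-D steady-state diagenesis with
piecewise-constant rates per zone, Dirichlet concentrations at both ends of
the domain, and constant porosity and Ds per solute. The solution is
piecewise quadratic in closed form; flux continuity and the global mass
balance J(0) − J(L) = φ·Σ R·thickness hold exactly, which makes the truth
object a machine-precision oracle for the estimators. Scenarios whose
analytic solution goes negative anywhere are rejected.

Measurement noise is additive Gaussian, truncated at zero, then censored at
the detection limit (a lognormal multiplicative model is available). The
default noise level is DL/3 per solute, i.e. the convention that a detection
limit is about three standard deviations of measurement noise; a noise level
equal to the DL would contradict the meaning of the DL and floods the
censoring boundary with spurious detections.

The presets encode the two observed core topologies. Depleting solutes
(O₂, NO₃⁻, NH₄⁺) are constructed directly as C¹ piecewise-quadratic
profiles — a quasi-linear limb, a convex consumption layer ending at a
vertex, and a sub-detection plateau — with the zone rates read off the
curvature; this guarantees positivity and puts the detection-limit crossings
at the stated depths (GS14-like: O₂ ~22 cm, NO₃⁻ ~130 cm, NH₄⁺ first
detectable ~213 cm; GS16-like: ~110 cm, ~191 cm, ~120 cm). Nitrite rates in
the sink/source/sink zones are obtained by a linear solve that pins the
profile at three (depth, concentration) points, e.g. a 3.3 µM maximum near
105 cm for GS14-like and a 1 µM maximum near 175 cm for GS16-like;
rate-free buffer zones keep both detection-limit crossings on linear limbs.
The quasi-linear nitrate decline matters: a profile that approaches its
detection limit flatly makes the near-crossing gradient windows
noise-dominated, which is unphysical for these cores and destabilises the
ratio statistic.

A separate `recovery_scenario` places the nitrate crossing deep inside a
weakly curved layer (vertex ~80 cm below the crossing) so that the
three-point window error is proportional to the grid spacing; it drives the
grid-refinement property (error monotone in h over 4, 2, 1, 0.5 cm, under 5%
at 2 cm).

Communities: expected composition is Gaussian bumps per family over a
background simplex (Dirichlet weights drawn once per scenario), observed
compositions are multinomial at 20,000 reads per horizon — the conventional
amplicon subsampling depth — and total 16S-derived cells decline
log-linearly from 10⁹ cells g⁻¹ at the surface at 0.004 decades cm⁻¹ (one
order of magnitude per 2.5 m, within the range observed in pelagic
sediments). That decay rate also keeps the sampled absolute-abundance maxima
on the prescribed peak depths, so the preset peak geometry (GS14-like: 11%
at 50 cm and 18% at 160 cm, 110 cm apart; GS16-like: peaks 45 cm apart) is
recovered exactly by `family_peaks` in the noise-free limit. The qPCR (hzo)
series is the summed-family truth with lognormal noise of 0.3 decades;
other marker genes (narG, nirS, nirK, amoA) are fixed small fractions of the
total community, present so the table is structurally complete. All
randomness flows from one seeded generator in a documented order, making
every artifact byte-reproducible.

## Statistical behaviour of the ratio estimator

The per-site ratio is a quotient of window slopes, so its sampling behaviour
depends on how well the grid resolves the profile limbs. At 10 cm sampling —
the scale at which such cores are actually subsampled — the estimator is
unbiased over noise replicates (the suite checks the 100-seed mean against
the noise-free value at one Monte-Carlo standard error). At much finer grids
the three-point windows shrink until the concentration difference across a
window is comparable to measurement noise, and at much coarser grids the
detection-edge discreteness (which sample is the last detectable one) makes
the estimator's distribution multimodal; neither regime is a sensible
operating point, and the replicate compilation in the acceptance script
therefore runs at 10 cm. Problem sizes used there — 121-point profiles for
zonation, 25-point profiles × 20 replicates for the compilation, 200
replicate multinomial draws, 100 random scenarios against the
finite-difference oracle — keep the whole suite in seconds while leaving the
Monte-Carlo errors far below the tested tolerances.

## Limitations

* Steady state only: no transient diagenesis, advection, compaction,
  bioturbation or bioirrigation terms.
* Reaction rates are piecewise-constant per zone; no kinetic coupling between
  solutes (the preset NH₄⁺ and NO₂⁻ sinks are geometrically, not
  stoichiometrically, linked).
* Censored values enter fits as 0 (or DL/2); no maximum-likelihood treatment
  of censoring.
* The synthetic communities have Gaussian family structure, a depth-constant
  background simplex and no compositional correlation between taxa; passing
  tests demonstrate correct arithmetic and estimator behaviour, not that real
  communities look like this.
* The field compilation statistics (the 30-site mean ratio) can only be
  reproduced with the study's deposited datasets, which this package does not
  ship; the suite validates the identical code path on synthetic stand-ins.
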