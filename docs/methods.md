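# Methods

This note records the models, conventions and numerical choices behind
`larvalsens`, and what its synthetic experiments do and do not demonstrate.

## Setting and scope

The toolkit targets the offline setting: a particle simulator driven by
archived z-level ocean-model output (daily-averaged horizontal velocities on
a regular lon/lat grid, depths following the Levitus convention of coarsening
spacing — 50 m steps within 150–300 m, 100 m within 300–1500 m, 250 m within
1500–2000 m, 500 m below). Vertical velocity is not part of such archives
and background vertical motion in the deep ocean is of order 10⁻⁵ cm s⁻¹
(< 1 m over a 100-day drift), so the tracker is purely horizontal at fixed
depth horizons. Diffusivity, larval behaviour and mortality are out of
scope: particles are passive, so sensitivity results isolate the physics of
the model pairing rather than biological parameter choices.

## Synthetic ocean

The generator supplies study conditions without external data. The domain
is a few-degree box at subpolar latitude containing an idealized guyot
(radially symmetric about its centre, flat summit at 600 m, linear flanks to
2000 m, 2500 m basin; summit radius 12 km, base radius 35 km).

Currents are built per snapshot from a streamfunction

ψ(x, y, t) = Σₑ sₑ aₑ(t) exp(−rₑ²/2L²),

a sum of Gaussian vortices of alternating sign sₑ, plus a uniform background
flow expressed as a linear streamfunction. Per z-level k the streamfunction
is scaled by an amplitude profile A(z) and multiplied by a taper σₖ that
falls smoothly to zero over three grid cells approaching the level's masked
(seafloor) region, after subtracting the wall-band mean of ψ; each level's
isobath is then a streamline, the flow deflects around the seamount, and the
residual wall jet carries only the along-wall variation of ψ. Velocities
are the *discrete central-difference* curl of ψσ (lon metric frozen at the
domain-centre latitude), so the discrete horizontal divergence vanishes
identically — the flow has no artificial particle sources or sinks, which
matters because the tracker is 2-D. Masked cells carry u = v = 0 so
interpolation is total.

Temporal evolution: each vortex strength follows an Ornstein–Uhlenbeck
process (mean 1, s.d. 0.4, e-folding 2 days — daily-averaged mid-latitude
currents decorrelate on roughly that scale, which is also what makes release
frequency a non-trivial parameter), and centres random-walk at 3 km day⁻¹
RMS with reflection at the domain walls. A single seeded generator drives
everything; identical inputs give bit-identical fields.

Defaults (units; rationale):

| parameter | default | why |
|---|---|---|
| grid spacing | 0.08° | the archived-output resolution emulated |
| amplitude profile A(z) | 0.05 / 0.50 / 0.32 / 1.00 / 0.15 / 0.10 at 0 / 200 / 700 / 1000 / 1500 / 5500 m | surface-intensified upper layer, mid-depth mesoscale maximum, quiescent deep water: variability greatest at 1000 m, least at 1500 m |
| ψ peak amplitude | 1.2 × 10⁴ m² s⁻¹ | peak swirl ≈ A/(L√e) ≈ 0.3 m s⁻¹ at the 1000 m maximum, drifter-like |
| eddy length scale L | 24 km (uniform) | mesoscale; an optional depth profile exists but patchier mid-depth coverage destabilizes small designs |
| eddy count | 24 per ≈5°×4.5° (50 at reference domain) | keeps eddy *density* constant so release rings are reliably sampled in every realization |
| background flow | (0.015, 0.005) m s⁻¹ | weak deep mean drift; advects without separating pairs |
| strength decorrelation | 2 days | see above |
| centre drift | 3 km day⁻¹ | slow eddy propagation |

The amplitude contrast (0.32 vs 1.00 between 700 and 1000 m) was calibrated
once so that the configured depth ordering of variability is statistically
recoverable by the suite's own estimator at demo problem sizes; the
qualitative ordering, not the absolute numbers, is the modelled feature.

## Tracker

Classical RK4 in degree space: d(lon)/dt = u/(m cos φ), d(lat)/dt = v/m with
m = πR/180 and R = 6371 km, each stage re-sampling the field at its own
position and time. Spatial interpolation is bicubic (4-point Lagrange,
separable) falling back to bilinear whenever the 4×4 stencil touches a
masked cell or the domain edge — the standard near-land degradation of
offline simulators — then linear in depth between bracketing z-levels and
linear in time between snapshots. Default timestep 1 h; daily output
including the release position, so a P-day drift yields P + 1 records.

A particle whose stage position leaves the grid or time span is frozen at
its last valid position and flagged `escaped`; one whose interpolated
seafloor is shallower than its depth by more than *half the local z-level
spacing* is frozen and flagged `beached`. The half-spacing tolerance is the
vertical granularity at which a z-level archive can distinguish water from
seafloor; a strict comparison would strand interface releases on the first
interpolation jitter. Frozen particles keep emitting their last position so
replicate designs stay balanced in both analyses. Everything is vectorized
over particles (each with its own release time), which is what makes
multi-thousand-track designs run in minutes.

## Designs

Release rings are placed at equal angular spacing about a depth contour's
centre (id 0 due north, clockwise), with the centre found by cancelling the
first angular harmonic of the contour radius (the coordinate mean of points
on a spherical circle is biased tens of metres equator-ward, so a
circumcentre iteration is required) and each point radially refined by
root-finding on the topography, using exact spherical destination/azimuth
geometry. Horizontal increments are interpreted as a buffer radius in
degrees: the increment point sits at along-contour arc length
offset × (π/180) × R clockwise of its baseline, on the same contour, so it
keeps interfacing with the seamount; successive offsets are additive to
≈10⁻⁹ degrees. Vertical increments displace depth only (shallower).

The sensitivity suite stands releases 250 m of seafloor clearance off the
wall (the ring is taken on the contour 250 m deeper than the release
depth). An archive-resolution model cannot resolve seafloor contact below a
grid cell, and analytically exact wall contact strands most particles on
discretization jitter rather than dispersing them; the stand-off reproduces
the effective geometry of cell-granular "interface" release sites.
Vertical-test baselines at 200 m (above the summit) reuse the summit-edge
ring horizontally.

Schedules use the printed per-year counts — daily 365 (regardless of leap
years), 2-daily 183, biweekly (read as twice weekly) 104, weekly 52, monthly
12, seasonal 4 — evenly spaced through a 365-day year. Temporal-range runs
enumerate all k-subsets of the simulated years, each tagged with its winter
NAO state where known (2009 neutral, 2010 strong negative, 2012 strong
positive; others "unclassified").

## Analyses

**DST.** Pairs are matched by (release point, release time); the per-day
haversine separation (R = 6371 km) covers days 1…P (day 0 is the imposed
offset). Pooling is over replicate locations, release times *and* all
tracking days, per depth band — never across depths. Frozen (beached or
escaped) positions enter as recorded; dropping them would unbalance the
design, and their retention is itself informative about wall interaction.
A shape-preserving piecewise cubic Hermite interpolant (PCHIP) through the
(increment, median) knots, anchored at zero separation for the baseline
increment, is intersected with the threshold (default 10 km) by dense
bracketing plus bisection to relative 10⁻⁶. If the curve never reaches the
threshold inside the tested range, the crossing of the end-slope linear
extrapolation is reported and flagged "(approx.)"; with a flat end slope
such extrapolations can be far beyond the tested range and should be read
as "coarser than everything tested", not as point estimates. A per-day
variant (median separation per tracking day) exposes how the usable
separation depends on PLD.

**FUV.** Each track's daily polyline is rasterized by exact segment–grid
traversal (Amanatides–Woo marching) into 0.04° cells — half the emulated
field resolution — with at most one count per track per cell, so counts
measure pathway coverage, not residence. Exact traversal (rather than point
sampling) matters because a day's displacement can skip cells. The raster
extent is the fixed analysis domain from the configuration. FUV = 1 − r²
with r the Pearson correlation over cells nonzero in at least one raster;
jointly empty cells depend only on the arbitrary extent and would inflate
r. r is reported alongside so anti-correlation stays visible; a
zero-variance raster raises rather than silently returning. The replicate
unit is the release location (its releases pooled into one raster pair).
Per increment the 95th percentile of replicate FUVs (linear-interpolation
quantile between order statistics) forms the envelope; the optimum is the
smallest increment where the PCHIP envelope first drops to ≤ 0.05, shared
crossing machinery with DST, down-crossing direction, same extrapolation
flag. r = √(1 − FUV) converts an envelope value back to a correlation.

**Workbench.** Suite order is TS → RF → HS/VS → TR: a wrong timestep would
contaminate every other test, and an under-seeded schedule would understate
the current variability the spatial tests probe. The Courant number
C = V̄ΔT/ΔL and the implied speed (optimal separation in metres at ring
latitude over optimal timestep) are provided as cross-checks; the implied
speed is only computed from non-extrapolated optima. Reports are
deterministic given the seed; a failing test is recorded and the suite
continues.

## Problem sizes

The reference configuration reproduces the standard design — 16 release
points per band at 700/1000/1500 m (200/1000/1750 m for the vertical test),
12 monthly releases through one year, 100-day PLD, 1-hour timestep, 2880
particles per baseline/increment pairing — and runs the three spatial tests
in ≈3 minutes on one CPU. Saturation tests at a daily-release baseline and
a five-year temporal range are supported by the same code but are memory-
and time-hungry at full scale, so the demo configuration used by the worked
examples, the acceptance script and the stochastic tests scales them down:
8 points per band, 8 releases per year, 60-day PLD, 2-hour timestep, weekly
release-frequency baseline (52 vs 26/12/4), two-year temporal range, and a
horizontal sweep extended to 0.05° so crossings fall inside the tested
range at that PLD. Parameter-recovery experiments repeat the demo suite
over 20 seeds (tests) or 12 seeds (acceptance script).

## What passing tests show — and what they don't

The synthetic ocean emulates the *structure* of archived hydrodynamic
output (grid, z-levels, daily snapshots, seamount mask, a mid-depth
variability maximum, ~2-day decorrelation), not any real region's currents:
there are no tides, no submesoscale, no vertical shear beyond the amplitude
profile, single-scale eddies, and vertically coherent (columnar) eddy
cores. Recovered optimal values therefore validate the *process* — that
the estimators recover a configured variability structure from trajectories
alone — and transfer to real data only as method, not as numbers. On real
archives one should expect rougher velocity fields at grid scale (hence far
smaller timestep optima than the smooth synthetic fields yield), and
beach/escape rates specific to the real topography.

Known limitations: optimal values inherit estimator noise from finite
replicates (flagged extrapolations especially); the along-contour offset
uses the local circle approximation (exact on the idealized guyot, approximate
on irregular contours); multi-lobed or open contours are not supported;
and the tracker deliberately omits diffusivity, so identical releases give
identical tracks and "particles per spawning event" is not a testable
parameter here.
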