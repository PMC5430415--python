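# Methods

## Model structure

The engine is a weekly-resolution growth/stress model of long-term
climatic favourability.  A year is exactly 52 weeks of 7 days (364 days),
which keeps all degree-day and stress arithmetic exact.  Monthly
climatologies are brought to the weekly timestep in two ways:

* **Point quantities** (temperatures, humidities) are linearly
  interpolated between month midpoints, with December wrapping to
  January.  Month *m* occupies weeks [m, m+1)·52/12 and its midpoint sits
  at (m+½)·52/12; weeks sample at their centres.  A constant input is
  reproduced exactly.
* **Totals** (precipitation) are split across the weeks each month
  overlaps, in proportion to overlap, so the annual sum is conserved to
  machine precision.

Weekly growth is TI_w · MI_w with both indices trapezoidal (0 below the
lower threshold, 1 on the optimum plateau, 0 above the upper threshold,
linear between).  The temperature index uses the weekly *mean*
temperature; cold stress uses the weekly *minimum* and heat stress the
weekly *maximum*, because survival limits bind at the extremes while
development tracks average conditions.  Stress accumulates linearly —
weekly increment |rate| × exceedance, summed, scaled by 100, capped at
100 — and is not compounded.  The stress-interaction term is fixed to 1
and no diapause index is modelled (the species is wet-tropical).

EI = GI_A × SI is forced to zero, with every satisfied condition
recorded, when (1) annual degree-days above DV0 fall below PDD (fewer
than one generation), (2) CS ≥ 100, (3) TI is zero in every week, or
(4) MI is zero in every week.  A fifth route to EI = 0 exists that the
four conditions do not cover: TI and MI can each be positive in some
week yet never in the *same* week (moisture available only in the cold
season), giving GI_A = 0.  These "seasonal mismatch" cells are reported
as zero-growth rather than being forced under one of the four flags;
likewise DS/HS/WS = 100 zero EI through SI without a dedicated flag.

### Parameters

All seventeen species parameters (DV0–DV3, SM0–SM3, TTCS/THCS,
TTHS/THHS, SMDS/HDS, SMWS/HWS, PDD) live in `SpeciesParams`, serialised
as a flat `KEY = value` text file using the standard mnemonics.  Stress
rates are stored with their conventional signs (cold and dry rates
negative); magnitudes are taken at the point of use, so accumulation is
sign-safe.  The wet-tropical template's PDD of 0 means "no generation
requirement" and is represented by an explicit disabled flag rather than
the number 0, avoiding a division by zero.  The fitted set for
*E. fornicatus* encodes the species' biology: development ceases below
15 °C, activity is optimal at 26–35 °C, and one generation needs 373
degree-days (≈237 DD egg-to-adult plus ≈136 DD preoviposition).

### Soil-moisture bucket

Soil moisture is a fraction of a 100 mm bucket, stepped weekly as
`sm ← clip(sm + (rain − evap)/capacity, 0, SM3 + 1)`; the cap above 1
expresses waterlogging (the wet-side response extends to SM3 = 2.5).
Evaporative demand is deliberately simple:
`E = max(0, k·T̄)·(1 − r̄h/100)·7` mm/week with k = 0.8 mm·day⁻¹·°C⁻¹
(configurable); demand vanishes at or below 0 °C and in saturated air.
The annual cycle is iterated to its periodic steady state.  Because the
bucket has no drainage term it is a pure integrator: a year in which
neither the floor nor the cap engages shifts the state by the annual
water balance.  Such drift-only years are skipped analytically (the
state jumps to the first year in which a bound engages), so the steady
state is reached in a handful of cycles and is independent of the
initial level for every cell with a non-zero annual balance.  Budgets
balancing to within 1e-9 of capacity per year are treated as already in
equilibrium — a dead-band that stops floating-point dust from being
amplified into a spurious drift to the floor or cap.  Exactly balanced
climates therefore hold their initial level (0.5, mid-bucket); this is
what makes constant-climate closed-form checks well-posed.

## Synthetic study region

`generate_synthetic_region` emulates the climate structure of a
subtropical-to-temperate monsoon country on a configurable lon/lat grid
(defaults: 50 × 50 cells of 0.5° from 97°E/18°N).  Fields, with every
constant housed in `SyntheticConfig`:

* annual mean temperature 24 °C at the southern edge, cooling 0.7 °C per
  degree of latitude; seasonal half-range growing from 4 °C in the south
  by 0.5 °C per degree northward (July peak);
* a smooth-edged western high plateau (4200 m) over otherwise low ground
  (300 m), cooled by a 6.5 °C/km lapse rate;
* annual rainfall falling from 1600 mm at the southeast corner to 60 mm
  at the northwest corner, concentrated in a July-centred monsoon peak;
  diurnal temperature range widening with dryness (8–12 °C);
* relative humidity tracking wetness (35–85% mean, 09:00 above 15:00 by
  16 points);
* smooth seeded Gaussian noise on temperature, wetness and elevation.

The future scenario warms tmax by +1.0 °C and tmin by +1.2 °C, scales
January–September precipitation by 1.05 and leaves humidity unchanged
(the near-term humidity response is treated as unknown).  The generator
is bit-deterministic given (grid, seed, scenario).

What the generator does *not* emulate: coastlines and oceanic buffering,
real station density and observation error, orography beyond one
plateau block, interannual variability, and the spatial covariance of
real monsoon systems.  Tests passing on these grids therefore
demonstrate correctness and qualitative behaviour of the method — index
arithmetic, limiting-factor attribution, directional response to a
prescribed warming — not predictive accuracy for any real landscape.

A note on the warming response: across seeds the potential range grows
and the highly-favourable class's area-weighted latitude centroid moves
north by a few tenths of a degree to ~1.5°.  Because the centroid is
dominated by the large, static southern block, individual noise
realisations can expand the class south of the centroid (warming lifts
winter TI) as much as north of it, leaving the domain centroid
essentially unmoved; frontier-region shifts are the more sensitive
diagnostic, which is why `range_shift` accepts a region mask.

## Spatial handling

Grids are regular lon/lat with cell areas (111.32·Δ)²·cos(latitude) km².
Station-to-grid interpolation is inverse-distance weighting over the k
nearest stations (great-circle distances, spherical Earth of 6371 km),
with temperatures reduced to sea level by the lapse rate before
averaging and re-elevated to the cell afterwards; a cell within 1e-6 km
of a station takes its values exactly.  Future climates are built by
additive anomaly calibration — observed baseline + (GCM future − GCM
baseline) — with precipitation floored at 0, humidity clipped to
[0, 100] and tmax/tmin ordering restored by swapping (counted and
logged).  Gridded I/O is long-format CSV with a self-describing header;
round-trips are bit-exact (`float_precision="round_trip"` on read).

## Analysis conventions

* **Classification**: EI = 0 unfavourable; (0, 10] marginal; (10, 20]
  favourable; > 20 highly favourable.  The boundary 20 belongs to
  favourable (the banding definition wins over loose "EI > 20" phrasing
  in map legends).
* **Impact index**: round-half-up of 10 × (affected area / region area),
  on areas rather than cell counts.
* **Range shift**: area-weighted latitude centroid displacement of a
  class, positive northward; undefined (None, not 0) when the class is
  absent from either scenario.
* **Point-in-cell**: a point on a cell edge belongs to the nearest cell
  centre, ties to the south-west.
* **Sensitivity**: one-at-a-time sweeps of DV0–DV3, TTCS, PDD, SM0–SM3 at
  ±5% and ±10% of the fitted value by default (the original perturbation
  magnitudes are not published, so they are configurable); mean EI over
  all unmasked cells including zeros.  Perturbed sets violating the
  parameter invariants are skipped with a logged reason.  The measured
  direction for DV1 on the synthetic grids is *negative* (a wider
  sub-optimal ramp raises EI at cool sites), which is what a trapezoidal
  TI implies; it is reported, never asserted.

## Problem sizes and numerics

The default study grid is 50 × 50 cells (2500 climatologies, each 52
weeks), which the vectorised engine evaluates in well under a second;
sensitivity sweeps rerun the engine ~40 times.  Floating-point checks in
tests use 1e-9 relative tolerance unless a looser bound is stated;
bucket spin-up converges when the largest weekly change between
consecutive years is below 1e-6 (at most 50 cycles, normally far fewer
thanks to the drift-skipping step).

## Known limitations

* The evaporation formulation is a one-constant stand-in for a proper
  Priestley–Taylor/Penman demand; only its response shape (increasing in
  temperature, vanishing in saturated air) is relied on.
* The bucket's bang-bang equilibria mean constant climates sit at the
  floor, the cap, or their initial level; realistic seasonal cycles move
  through the favourable range, but absolute EI levels on synthetic
  grids should not be read as calibrated.
* IDW with a single lapse rate replaces thin-plate-spline climate
  surfaces; fine for the package's testing role, not for production
  interpolation of dense station networks.
* No diapause, irrigation, stress interaction, or host-distribution
  constraints.
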