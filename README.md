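# ecoclimex

Mechanistic ecoclimatic suitability modelling for the polyphagous
shot-hole borer, *Euwallacea fornicatus* (Coleoptera: Curculionidae), a
quarantine forest pest of tea, avocado, lychee and many broadleaf street
trees.  The package is aimed at pest-risk analysts and ecologists who want
a transparent, scriptable CLIMEX-style "compare locations" pipeline: given
a monthly climatology it predicts where the beetle can persist, why it
cannot persist elsewhere, and how a warmed climate changes the picture.

## The model

For each location the year is resolved into 52 weeks.  Weekly population
growth potential is the product of two 0–1 trapezoidal responses: a
temperature index TI(T̄) rising from the lower development threshold
DV0 = 15 °C to an optimum plateau on [DV1, DV2] = [26, 35] °C and falling
to zero at DV3 = 40 °C, and a soil-moisture index MI(SM) over
SM0–SM3 = 0.05, 0.3, 1, 2.5 (fractions of a 100 mm bucket, values above 1
expressing waterlogging).  Soil moisture follows a weekly bucket balance
driven by rainfall and a temperature/humidity evaporative demand, iterated
to its periodic annual steady state.

The Annual Growth Index is GI_A = 100 · mean_w(TI_w · MI_w).  Four
stresses accumulate linearly beyond thresholds at fixed weekly rates —
cold (TTCS = −10 °C on weekly minima, rate 0.005 wk⁻¹), heat (TTHS = 42 °C
on weekly maxima), dry (SMDS = 0.05) and wet (SMWS = 2.5) — each capped at
100.  They combine into the Annual Stress Index

    SI = (1 − CS/100)(1 − DS/100)(1 − HS/100)(1 − WS/100)

and the Ecoclimatic Index is

    EI = GI_A × SI        (0–100)

forced to 0, with a recorded limiting factor, whenever generations < 1
(annual degree-days above DV0 below PDD = 373 DD), CS ≥ 100, TI = 0 all
year, or MI = 0 all year.  EI is banded into unfavourable (EI = 0),
marginally favourable (0 < EI ≤ 10), favourable (10 < EI ≤ 20) and highly
favourable (EI > 20) habitat.

Around the engine the package provides station-CSV reading, IDW
interpolation to regular lon/lat grids with a lapse-rate elevation
adjustment, additive GCM anomaly ("delta") calibration of future
climates, a deterministic synthetic monsoon-region climate generator,
area/limiting-factor/impact summaries, range-shift and EI-change
comparisons, occurrence validation, and one-at-a-time parameter
sensitivity sweeps.

## Worked example

```python
import ecoclimex as ec

p = ec.default_fornicatus_params()          # Table of fitted parameters
evap = 0.8 * 29 * 0.25 * 7                  # weekly evaporative demand, mm
mc = ec.MonthlyClimate(tmax=[34.0]*12, tmin=[24.0]*12,
                       precip=[evap * 52 / 12]*12,   # balanced water budget
                       rh09=[85.0]*12, rh15=[65.0]*12)
r = ec.run_location(mc, p)
print(f"EI={r.ei:.2f} GI_A={r.gi_a:.2f} CS={r.cs:.1f} HS={r.hs:.1f} "
      f"DS={r.ds:.1f} WS={r.ws:.1f} generations={r.generations:.2f} "
      f"flags={r.limiting_flags}")
```

prints

```
EI=100.00 GI_A=100.00 CS=0.0 HS=0.0 DS=0.0 WS=0.0 generations=13.66 flags=()
```

— a constant 29 °C year inside the optimal temperature plateau, with rain
exactly offsetting evaporative demand, is the incubator-like ideal: full
growth every week, no stress, 13.7 generations per year, EI at its ceiling
of 100.

The command-line pipeline runs whole grids.  On the built-in synthetic
monsoon region (50 × 50 cells of 0.5°, warm wet southeast, cold north,
dry northwest, high western plateau):

```sh
$ ecoclimex run --seed 1
scenario=current cells=2500 mean_EI=1.973 suitable_cells=682/2500
```

`ecoclimex compare` adds the future scenario (tmax +1.0 °C, tmin +1.2 °C,
Jan–Sep precipitation +5%) and writes ΔEI grids, per-class area changes,
class-transition counts and northward range shifts; `ecoclimex validate`
scores occurrence records against the suitability classes; `ecoclimex
sensitivity` sweeps the ten response parameters.

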