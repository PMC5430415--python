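"""Weekly growth/stress engine computing the Ecoclimatic Index (EI).

The engine turns a 12-month climatology into a 52-week internal year
(exactly 52 weeks × 7 days = 364 days, which keeps the arithmetic exact),
evaluates weekly temperature and soil-moisture growth responses, accumulates
the four climatic stresses, and combines them into an annual index

    EI = GI_A × SI,          SI = (1−CS/100)(1−DS/100)(1−HS/100)(1−WS/100)

on a 0–100 scale (the stress-interaction term is fixed to 1, following
common practice).  EI is forced to 0, with a flag recording the cause,
whenever any of four limiting conditions holds: fewer than one generation
per year (degree-days below PDD), cold stress ≥ 100, a temperature index
of zero in every week, or a moisture index of zero in every week.

All numerical kernels broadcast over leading axes, so a whole grid of
cells is evaluated as arrays of shape ``(n_cells, 52)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .params import SpeciesParams

__all__ = [
    "MonthlyClimate",
    "CellResult",
    "interpolate_weekly",
    "temperature_index",
    "weekly_evaporation",
    "update_soil_moisture",
    "spin_up_soil_moisture",
    "moisture_index",
    "annual_growth_index",
    "accumulate_stress",
    "annual_stress_index",
    "degree_days_and_generations",
    "run_location",
    "run_cells",
]

N_WEEKS = 52
DAYS_PER_WEEK = 7.0
#: Soil bucket capacity in mm; moisture is expressed as a fraction of this.
DEFAULT_BUCKET_CAPACITY = 100.0
#: Evaporative-demand constant, mm·day⁻¹·°C⁻¹ of weekly mean temperature.
DEFAULT_EVAP_K = 0.8

LIMITING_FLAGS = ("GEN_LT_1", "CS_GE_100", "TI_ZERO", "MI_ZERO")


@dataclass(frozen=True)
class MonthlyClimate:
    """Monthly climatology for one location.

    tmax, tmin in °C, precip in mm/month, rh09/rh15 in % (relative humidity
    at 09:00 and 15:00); each field holds 12 values, January first.
    """

    tmax: np.ndarray
    tmin: np.ndarray
    precip: np.ndarray
    rh09: np.ndarray
    rh15: np.ndarray

    def __post_init__(self):
        for name in ("tmax", "tmin", "precip", "rh09", "rh15"):
            a = np.asarray(getattr(self, name), dtype=float)
            if a.shape != (12,):
                raise ValueError(f"{name} must hold 12 monthly values")
            if not np.all(np.isfinite(a)):
                raise ValueError(f"{name} contains non-finite values")
            object.__setattr__(self, name, a)

    def violations(self) -> list[str]:
        v = []
        if np.any(self.tmax < self.tmin):
            bad = np.nonzero(self.tmax < self.tmin)[0] + 1
            v.append(f"tmax < tmin in month(s) {list(bad)}")
        if np.any(self.precip < 0):
            v.append("negative precipitation")
        for name in ("rh09", "rh15"):
            a = getattr(self, name)
            if np.any((a < 0) | (a > 100)):
                v.append(f"{name} outside [0, 100]")
        return v


@dataclass
class CellResult:
    """Annual engine outputs for one cell.

    ``ei`` is on the 0–100 scale; ``limiting_flags`` lists every satisfied
    zero-EI condition (a cell can satisfy several at once).
    """

    gi_a: float
    cs: float
    hs: float
    ds: float
    ws: float
    si: float
    dd_annual: float
    generations: float
    ei: float
    limiting_flags: tuple[str, ...]
    weekly: Optional[pd.DataFrame] = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# monthly -> weekly interpolation

def _month_midpoints() -> np.ndarray:
    # month m spans [m, m+1) * 52/12 in week units; midpoint at its centre
    return (np.arange(12) + 0.5) * N_WEEKS / 12.0


def _point_interp_weights() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-week source months and linear weight for point quantities."""
    mids = _month_midpoints()
    wk = np.arange(N_WEEKS) + 0.5
    # periodic: offset by half a month so searchsorted lands in [0, 12)
    m1 = np.searchsorted(mids, wk) % 12
    m0 = (m1 - 1) % 12
    span = N_WEEKS / 12.0
    dist = (wk - mids[m0]) % N_WEEKS
    t = dist / span
    return m0, m1, t


def _total_split_matrix() -> np.ndarray:
    """(52, 12) matrix of overlap fractions: week w gets this share of month m."""
    w = np.zeros((N_WEEKS, 12))
    month_edges = np.arange(13) * N_WEEKS / 12.0
    for wk in range(N_WEEKS):
        lo, hi = float(wk), float(wk + 1)
        for m in range(12):
            a, b = month_edges[m], month_edges[m + 1]
            overlap = max(0.0, min(hi, b) - max(lo, a))
            if overlap > 0:
                w[wk, m] = overlap / (b - a)
    return w


_M0, _M1, _T = _point_interp_weights()
_SPLIT = _total_split_matrix()


def interpolate_weekly(values, conserve_total: bool = False) -> np.ndarray:
    """Interpolate 12 monthly values to 52 weekly values.

    Point quantities (temperature, humidity) are linearly interpolated
    between month midpoints with December→January wrap-around; monthly
    totals (precipitation) are instead split across the weeks each month
    overlaps, so the annual sum is conserved exactly.

    ``values`` may carry leading axes; the last axis must be 12.
    """
    a = np.asarray(values, dtype=float)
    if a.shape[-1] != 12:
        raise ValueError("last axis must hold 12 monthly values")
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite monthly values")
    if conserve_total:
        return a @ _SPLIT.T
    # written so a constant input is reproduced exactly
    return a[..., _M0] + (a[..., _M1] - a[..., _M0]) * _T


# ---------------------------------------------------------------------------
# weekly response curves

def _trapezoid(x, a, b, c, d) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rise = (x - a) / (b - a)
        fall = np.where(d > c, (d - x) / (d - c), np.where(x < d, np.inf, 0.0))
    return np.clip(np.minimum(rise, fall), 0.0, 1.0)


def temperature_index(tavg, p: SpeciesParams) -> np.ndarray:
    """Weekly 0–1 temperature response: a trapezoid over DV0–DV3.

    Zero at/below ``dv0`` (immature stages cannot develop), optimal (1)
    between ``dv1`` and ``dv2``, zero at/above ``dv3``.
    """
    return _trapezoid(tavg, p.dv0, p.dv1, p.dv2, p.dv3)


def moisture_index(sm, p: SpeciesParams) -> np.ndarray:
    """Weekly 0–1 soil-moisture response: a trapezoid over SM0–SM3."""
    return _trapezoid(sm, p.sm0, p.sm1, p.sm2, p.sm3)


def weekly_evaporation(tavg, rh09, rh15, k: float = DEFAULT_EVAP_K) -> np.ndarray:
    """Evaporative demand in mm/week.

    A deliberately simple temperature-driven formulation:
    ``E = max(0, k·tavg) · (1 − rh̄/100) · 7`` with ``rh̄`` the mean of the
    09:00 and 15:00 relative humidities.  Demand vanishes at or below 0 °C
    and in saturated air.
    """
    tavg = np.asarray(tavg, dtype=float)
    rh_mean = (np.asarray(rh09, dtype=float) + np.asarray(rh15, dtype=float)) / 2.0
    return np.maximum(0.0, k * tavg) * (1.0 - rh_mean / 100.0) * DAYS_PER_WEEK


def update_soil_moisture(sm_prev, rain_w, evap_w, capacity: float = DEFAULT_BUCKET_CAPACITY,
                         sm_cap: float = 3.5) -> np.ndarray:
    """One weekly step of the soil-moisture bucket.

    ``sm`` is a fraction of bucket capacity; it is floored at 0 and capped
    at ``sm_cap`` (waterlogging above 1 is meaningful because the wet-side
    response extends beyond saturation).
    """
    if capacity <= 0:
        raise ValueError("bucket capacity must be positive")
    sm = np.asarray(sm_prev, dtype=float) + (np.asarray(rain_w, dtype=float)
                                             - np.asarray(evap_w, dtype=float)) / capacity
    return np.clip(sm, 0.0, sm_cap)


def spin_up_soil_moisture(rain, evap, capacity: float = DEFAULT_BUCKET_CAPACITY,
                          sm_cap: float = 3.5, sm_init: float = 0.5,
                          tol: float = 1e-6, max_cycles: int = 50) -> np.ndarray:
    """Iterate the 52-week bucket to its periodic steady state.

    The annual cycle is repeated (up to ``max_cycles`` years) until the
    largest weekly change between consecutive years falls below ``tol``;
    the converged year is returned, shape ``(..., 52)``.

    The yearly map is monotone piecewise-linear, so a cell whose floor and
    cap never engage simply drifts by its annual water balance; such years
    are skipped analytically (the state jumps straight to the year in which
    the floor or cap first engages), which makes the steady state
    independent of ``sm_init`` for every cell with a non-zero annual
    balance.  A cell whose annual budget balances to within 1e-9 of
    bucket capacity and never pins is treated as being in equilibrium and
    keeps its initial level — a measure-zero degeneracy with smooth
    climate fields (the dead-band stops floating-point dust in the budget
    from being amplified into a drift to the floor or cap).
    """
    if capacity <= 0:
        raise ValueError("bucket capacity must be positive")
    rain = np.asarray(rain, dtype=float)
    evap = np.asarray(evap, dtype=float)
    lead = np.broadcast_shapes(rain.shape[:-1], evap.shape[:-1])
    delta = np.broadcast_to((rain - evap) / capacity,
                            lead + (N_WEEKS,)).reshape(-1, N_WEEKS)
    cum = np.cumsum(delta, axis=-1)
    max_reach = cum.max(axis=-1)      # highest excursion within a pin-free year
    min_reach = np.minimum(0.0, cum.min(axis=-1))
    drift = cum[..., -1]              # net annual change when nothing pins
    n = delta.shape[0]

    sm = np.empty((n, N_WEEKS), dtype=float)
    prev_year = np.full((n, N_WEEKS), np.inf)
    state = np.full(n, float(sm_init))
    for _ in range(max_cycles):
        start = state
        pinned = np.zeros(n, dtype=bool)
        for w in range(N_WEEKS):
            raw = state + delta[..., w]
            pinned |= (raw < 0.0) | (raw > sm_cap)
            state = np.clip(raw, 0.0, sm_cap)
            sm[..., w] = state
        if np.max(np.abs(sm - prev_year)) < tol:
            break
        prev_year[...] = sm
        # skip drift-only years for cells that never touched floor or cap
        free = ~pinned & (np.abs(drift) > 1e-9)
        up = free & (drift > 0)
        if np.any(up):
            k = np.floor((sm_cap - max_reach[up] - state[up]) / drift[up])
            state[up] += drift[up] * np.maximum(0.0, k)
        down = free & (drift < 0)
        if np.any(down):
            k = np.floor((state[down] + min_reach[down]) / -drift[down])
            state[down] += drift[down] * np.maximum(0.0, k)
    return sm.reshape(lead + (N_WEEKS,))


# ---------------------------------------------------------------------------
# annual indices

def annual_growth_index(ti, mi) -> np.ndarray:
    """Annual Growth Index GI_A ∈ [0, 100]: 100 × mean weekly TI·MI."""
    ti = np.asarray(ti, dtype=float)
    mi = np.asarray(mi, dtype=float)
    if ti.shape[-1] != N_WEEKS or mi.shape[-1] != N_WEEKS:
        raise ValueError("weekly series must hold 52 values")
    return 100.0 * np.mean(ti * mi, axis=-1)


def accumulate_stress(series, threshold: float, rate: float, direction: str) -> np.ndarray:
    """Annual stress ∈ [0, 100] from weekly excursions beyond a threshold.

    The weekly increment is ``|rate| × exceedance``, where the exceedance is
    ``threshold − x`` for ``direction='below'`` (cold, dry) and
    ``x − threshold`` for ``direction='above'`` (heat, wet).  The annual sum
    is scaled by 100 and capped at 100 (lethal).
    """
    x = np.asarray(series, dtype=float)
    if direction == "below":
        exceed = np.maximum(0.0, threshold - x)
    elif direction == "above":
        exceed = np.maximum(0.0, x - threshold)
    else:
        raise ValueError(f"direction must be 'above' or 'below', got {direction!r}")
    return np.minimum(100.0, 100.0 * abs(rate) * exceed.sum(axis=-1))


def annual_stress_index(cs, ds, hs, ws) -> np.ndarray:
    """Annual Stress Index SI ∈ [0, 1], the product of the four survivals."""
    cs, ds, hs, ws = (np.asarray(s, dtype=float) for s in (cs, ds, hs, ws))
    for name, s in (("cs", cs), ("ds", ds), ("hs", hs), ("ws", ws)):
        if np.any((s < 0) | (s > 100)):
            raise ValueError(f"{name} outside [0, 100]")
    return (1 - cs / 100) * (1 - ds / 100) * (1 - hs / 100) * (1 - ws / 100)


def degree_days_and_generations(tavg, p: SpeciesParams) -> tuple[np.ndarray, np.ndarray]:
    """Annual degree-days above ``dv0`` and generations per year.

    Degree-days accumulate as weekly mean exceedance × 7 days; generations
    = DD / PDD.  With the generation requirement disabled the generation
    count is reported as +inf (never limiting).
    """
    tavg = np.asarray(tavg, dtype=float)
    dd = (np.maximum(0.0, tavg - p.dv0) * DAYS_PER_WEEK).sum(axis=-1)
    if p.pdd_enabled:
        gen = dd / p.pdd
    else:
        gen = np.full_like(dd, np.inf)
    return dd, gen


# ---------------------------------------------------------------------------
# full engine

def run_cells(tmax_m, tmin_m, precip_m, rh09_m, rh15_m, p: SpeciesParams,
              capacity: float = DEFAULT_BUCKET_CAPACITY,
              evap_k: float = DEFAULT_EVAP_K,
              return_weekly: bool = False) -> dict[str, np.ndarray]:
    """Run the engine over arrays of monthly climatologies.

    Inputs have shape ``(..., 12)`` (any common leading shape); returns a
    dict of annual arrays with that leading shape — ``ei``, ``gi_a``,
    ``cs``, ``hs``, ``ds``, ``ws``, ``si``, ``dd_annual``, ``generations``
    and one boolean mask per limiting condition.  With ``return_weekly``
    the weekly driver and index series (shape ``(..., 52)``) are included.
    """
    tmax = interpolate_weekly(tmax_m)
    tmin = interpolate_weekly(tmin_m)
    tavg = (tmax + tmin) / 2.0
    rain = interpolate_weekly(precip_m, conserve_total=True)
    rh09 = interpolate_weekly(rh09_m)
    rh15 = interpolate_weekly(rh15_m)

    evap = weekly_evaporation(tavg, rh09, rh15, k=evap_k)
    sm = spin_up_soil_moisture(rain, evap, capacity=capacity, sm_cap=p.sm3 + 1.0)

    ti = temperature_index(tavg, p)
    mi = moisture_index(sm, p)
    gi_a = annual_growth_index(ti, mi)

    # survival limits bind at the extremes: cold on tmin, heat on tmax
    cs = accumulate_stress(tmin, p.ttcs, p.thcs, "below")
    hs = accumulate_stress(tmax, p.tths, p.thhs, "above")
    ds = accumulate_stress(sm, p.smds, p.hds, "below")
    ws = accumulate_stress(sm, p.smws, p.hws, "above")
    si = annual_stress_index(cs, ds, hs, ws)

    dd, gen = degree_days_and_generations(tavg, p)

    flag_gen = gen < 1.0
    flag_cs = cs >= 100.0
    flag_ti = ti.sum(axis=-1) == 0.0
    flag_mi = mi.sum(axis=-1) == 0.0

    ei = gi_a * si
    ei = np.where(flag_gen | flag_cs | flag_ti | flag_mi, 0.0, ei)

    out = {
        "gi_a": gi_a, "cs": cs, "hs": hs, "ds": ds, "ws": ws, "si": si,
        "dd_annual": dd, "generations": gen, "ei": ei,
        "GEN_LT_1": flag_gen, "CS_GE_100": flag_cs,
        "TI_ZERO": flag_ti, "MI_ZERO": flag_mi,
    }
    if return_weekly:
        out.update({"tavg_w": tavg, "tmax_w": tmax, "tmin_w": tmin,
                    "rain_w": rain, "sm_w": sm, "ti_w": ti, "mi_w": mi,
                    "gi_w": ti * mi})
    return out


def run_location(mc: MonthlyClimate, p: SpeciesParams,
                 capacity: float = DEFAULT_BUCKET_CAPACITY,
                 evap_k: float = DEFAULT_EVAP_K,
                 return_weekly: bool = False) -> CellResult:
    """Run the engine for a single location's monthly climatology."""
    bad = mc.violations()
    if bad:
        raise ValueError("invalid climatology: " + "; ".join(bad))
    r = run_cells(mc.tmax, mc.tmin, mc.precip, mc.rh09, mc.rh15, p,
                  capacity=capacity, evap_k=evap_k, return_weekly=return_weekly)
    flags = tuple(f for f in LIMITING_FLAGS if bool(r[f]))
    weekly = None
    if return_weekly:
        weekly = pd.DataFrame({
            "week": np.arange(1, N_WEEKS + 1),
            "tavg": r["tavg_w"], "tmin": r["tmin_w"], "tmax": r["tmax_w"],
            "rain": r["rain_w"], "sm": r["sm_w"],
            "ti": r["ti_w"], "mi": r["mi_w"], "gi": r["gi_w"],
        })
    return CellResult(
        gi_a=float(r["gi_a"]), cs=float(r["cs"]), hs=float(r["hs"]),
        ds=float(r["ds"]), ws=float(r["ws"]), si=float(r["si"]),
        dd_annual=float(r["dd_annual"]), generations=float(r["generations"]),
        ei=float(r["ei"]), limiting_flags=flags, weekly=weekly,
    )
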