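"""Station and gridded monthly climatologies.

Provides the regular lon/lat grid container used throughout the package,
a station-CSV reader, inverse-distance-weighted (IDW) interpolation of
stations to a grid with a lapse-rate elevation adjustment, additive GCM
anomaly ("delta") calibration of future climates, and a deterministic
synthetic climate generator that emulates a monsoon-climate region: a
south-to-north cooling gradient, a southeast-to-northwest drying gradient
with a summer monsoon peak, and a cold high plateau in the west.

Grids are stored cell-flattened in row-major order with row 0 at the
southern edge and column 0 at the western edge
(``index = row * n_cols + col``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .engine import MonthlyClimate

logger = logging.getLogger(__name__)

__all__ = [
    "GridSpec",
    "StationRecord",
    "ClimateGrid",
    "SyntheticConfig",
    "read_station_csv",
    "idw_interpolate",
    "apply_gcm_delta",
    "generate_synthetic_region",
    "write_grid_csv",
    "read_grid_csv",
]

EARTH_RADIUS_KM = 6371.0
#: km per degree of latitude on the spherical Earth used for cell areas.
KM_PER_DEG = 111.32

CLIMATE_VARS = ("tmax", "tmin", "precip", "rh09", "rh15")


@dataclass(frozen=True)
class GridSpec:
    """Regular lon/lat grid: origin at the south-west corner of cell (0, 0)."""

    lon_origin: float
    lat_origin: float
    cell_size: float
    n_cols: int
    n_rows: int

    def __post_init__(self):
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_cols <= 0 or self.n_rows <= 0:
            raise ValueError("grid dimensions must be positive")

    @property
    def n_cells(self) -> int:
        return self.n_cols * self.n_rows

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) center coordinates for every cell, flattened."""
        lon = self.lon_origin + (np.arange(self.n_cols) + 0.5) * self.cell_size
        lat = self.lat_origin + (np.arange(self.n_rows) + 0.5) * self.cell_size
        lon2, lat2 = np.meshgrid(lon, lat)
        return lon2.ravel(), lat2.ravel()

    def cell_areas(self) -> np.ndarray:
        """Cell areas in km², shrinking with cos(latitude)."""
        _, lat = self.cell_centers()
        return (KM_PER_DEG * self.cell_size) ** 2 * np.cos(np.deg2rad(lat))

    def cell_index(self, lon, lat) -> np.ndarray:
        """Map points to flattened cell indices (-1 when outside the grid).

        A point on a cell edge belongs to the cell whose center is nearest;
        exact ties go to the south-west cell.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        u = (lon - self.lon_origin) / self.cell_size
        v = (lat - self.lat_origin) / self.cell_size
        col = np.floor(u).astype(int)
        row = np.floor(v).astype(int)
        # interior edge points sit exactly on an integer: tie -> south-west
        col = np.where((u == col) & (col > 0), col - 1, col)
        row = np.where((v == row) & (row > 0), row - 1, row)
        inside = (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        return np.where(inside, row * self.n_cols + col, -1)


@dataclass(frozen=True)
class StationRecord:
    """One meteorological station with its monthly climatology."""

    id: str
    lon: float
    lat: float
    elevation: float
    climate: MonthlyClimate

    def __post_init__(self):
        if not (-180 <= self.lon <= 180) or not (-90 <= self.lat <= 90):
            raise ValueError(f"station {self.id}: coordinates out of range")


@dataclass
class ClimateGrid:
    """Gridded monthly climatology: each variable is an ``(n_cells, 12)`` array."""

    spec: GridSpec
    tmax: np.ndarray
    tmin: np.ndarray
    precip: np.ndarray
    rh09: np.ndarray
    rh15: np.ndarray
    elevation: Optional[np.ndarray] = None
    mask: Optional[np.ndarray] = None  # True where the cell is valid

    def __post_init__(self):
        n = self.spec.n_cells
        for name in CLIMATE_VARS:
            a = np.asarray(getattr(self, name), dtype=float)
            if a.shape != (n, 12):
                raise ValueError(f"{name} must have shape ({n}, 12)")
            setattr(self, name, a)
        if self.mask is None:
            self.mask = np.ones(n, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        if self.elevation is not None:
            self.elevation = np.asarray(self.elevation, dtype=float)

    def cell_climate(self, i: int) -> MonthlyClimate:
        return MonthlyClimate(tmax=self.tmax[i], tmin=self.tmin[i],
                              precip=self.precip[i], rh09=self.rh09[i],
                              rh15=self.rh15[i])

    def violations(self) -> list[str]:
        """Invariant violations over all unmasked cells."""
        v = []
        m = self.mask
        if np.any(self.tmax[m] < self.tmin[m]):
            v.append("tmax < tmin in some unmasked cell/month")
        if np.any(self.precip[m] < 0):
            v.append("negative precipitation")
        for name in ("rh09", "rh15"):
            a = getattr(self, name)[m]
            if np.any((a < 0) | (a > 100)):
                v.append(f"{name} outside [0, 100]")
        return v


# ---------------------------------------------------------------------------
# station CSV

def _station_columns() -> list[str]:
    cols = ["id", "lon", "lat", "elev"]
    for var in ("tmax", "tmin", "prcp", "rh09", "rh15"):
        cols += [f"{var}{m:02d}" for m in range(1, 13)]
    return cols


def read_station_csv(path: Union[str, Path]) -> list[StationRecord]:
    """Read stations from a CSV with columns id, lon, lat, elev and 60
    climate columns (tmax01..tmax12, tmin.., prcp.., rh09.., rh15..).

    Missing columns and unparseable numbers are hard errors naming the
    column or line; rows whose climatology violates physical invariants
    (tmin > tmax, negative precipitation, RH outside 0–100) are parsed but
    reported through the module logger with their line numbers.
    """
    df = pd.read_csv(path, dtype={"id": str}, float_precision="round_trip")
    required = _station_columns()
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    records: list[StationRecord] = []
    for pos, row in df.iterrows():
        lineno = pos + 2  # header is line 1
        vals = {}
        for var, key in (("tmax", "tmax"), ("tmin", "tmin"), ("precip", "prcp"),
                         ("rh09", "rh09"), ("rh15", "rh15")):
            try:
                vals[var] = np.array(
                    [float(row[f"{key}{m:02d}"]) for m in range(1, 13)])
            except (TypeError, ValueError) as e:
                raise ValueError(f"{path}:{lineno}: unparseable {key} value") from e
        mc = MonthlyClimate(**vals)
        bad = mc.violations()
        if bad:
            logger.warning("%s:%d: station %s: %s", path, lineno, row["id"],
                           "; ".join(bad))
        records.append(StationRecord(id=str(row["id"]), lon=float(row["lon"]),
                                     lat=float(row["lat"]),
                                     elevation=float(row["elev"]), climate=mc))
    return records


# ---------------------------------------------------------------------------
# IDW interpolation

def great_circle_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Haversine great-circle distance in km on a sphere of radius 6371 km."""
    lon1, lat1, lon2, lat2 = (np.deg2rad(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


def idw_interpolate(stations: Sequence[StationRecord], spec: GridSpec,
                    power: float = 2.0, k_neighbors: int = 8,
                    lapse_rate: float = 6.5,
                    grid_elevation: Optional[np.ndarray] = None) -> ClimateGrid:
    """Interpolate station climatologies to a grid by inverse-distance
    weighting over the k nearest stations (great-circle distances).

    Temperatures are reduced to sea level with ``lapse_rate`` (°C/km),
    interpolated, then re-elevated to the cell elevation, so elevation
    contrasts survive the interpolation.  A cell closer than 1e-6 km to a
    station takes that station's values exactly.
    """
    if len(stations) == 0:
        raise ValueError("at least one station is required")
    if power <= 0:
        raise ValueError("power must be positive")
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    if k_neighbors > len(stations):
        logger.warning("k_neighbors=%d clamped to %d stations",
                       k_neighbors, len(stations))
        k_neighbors = len(stations)

    lon_c, lat_c = spec.cell_centers()
    if grid_elevation is None:
        grid_elevation = np.zeros(spec.n_cells)
    grid_elevation = np.asarray(grid_elevation, dtype=float)

    st_lon = np.array([s.lon for s in stations])
    st_lat = np.array([s.lat for s in stations])
    st_elev = np.array([s.elevation for s in stations])

    data = {}
    for var in CLIMATE_VARS:
        key = "precip" if var == "precip" else var
        data[var] = np.stack([getattr(s.climate, key) for s in stations])
    # reduce temperatures to sea level before averaging
    for var in ("tmax", "tmin"):
        data[var] = data[var] + lapse_rate * st_elev[:, None] / 1000.0

    d = great_circle_km(lon_c[:, None], lat_c[:, None],
                        st_lon[None, :], st_lat[None, :])  # (cells, stations)
    near = np.argsort(d, axis=1)[:, :k_neighbors]
    dn = np.take_along_axis(d, near, axis=1)
    with np.errstate(divide="ignore"):
        w = dn ** (-power)
    # coincident station: exact assignment
    exact = dn < 1e-6
    has_exact = exact.any(axis=1)
    w = np.where(exact, 1.0, w)
    w[has_exact] *= exact[has_exact]
    w /= w.sum(axis=1, keepdims=True)

    out = {}
    for var in CLIMATE_VARS:
        vals = data[var][near]                       # (cells, k, 12)
        out[var] = np.einsum("ck,ckm->cm", w, vals)
    for var in ("tmax", "tmin"):
        out[var] = out[var] - lapse_rate * grid_elevation[:, None] / 1000.0
    return ClimateGrid(spec=spec, elevation=grid_elevation.copy(), **out)


# ---------------------------------------------------------------------------
# GCM delta calibration

def apply_gcm_delta(baseline_obs: ClimateGrid, gcm_baseline: ClimateGrid,
                    gcm_future: ClimateGrid) -> ClimateGrid:
    """Calibrated future climate: observed baseline + (GCM future − GCM baseline).

    The additive anomaly avoids GCM bias in absolute values.  Precipitation
    is floored at 0, relative humidity clipped to [0, 100], and any cell
    where the deltas invert the tmax/tmin ordering has the pair swapped
    (the number of swaps is logged).
    """
    if not (baseline_obs.spec == gcm_baseline.spec == gcm_future.spec):
        raise ValueError("all three grids must share one GridSpec")
    out = {}
    for var in CLIMATE_VARS:
        delta = getattr(gcm_future, var) - getattr(gcm_baseline, var)
        out[var] = getattr(baseline_obs, var) + delta
    out["precip"] = np.maximum(0.0, out["precip"])
    for var in ("rh09", "rh15"):
        out[var] = np.clip(out[var], 0.0, 100.0)
    inverted = out["tmax"] < out["tmin"]
    n_swap = int(inverted.sum())
    if n_swap:
        logger.warning("apply_gcm_delta: tmax/tmin ordering restored in %d "
                       "cell-months", n_swap)
        lo = np.where(inverted, out["tmax"], out["tmin"])
        hi = np.where(inverted, out["tmin"], out["tmax"])
        out["tmin"], out["tmax"] = lo, hi
    elev = None if baseline_obs.elevation is None else baseline_obs.elevation.copy()
    return ClimateGrid(spec=baseline_obs.spec, elevation=elev,
                       mask=baseline_obs.mask.copy(), **out)


# ---------------------------------------------------------------------------
# synthetic region generator

@dataclass(frozen=True)
class SyntheticConfig:
    """Constants of the synthetic monsoon-region climate.

    The defaults sketch a subtropical-to-temperate monsoon region: annual
    mean temperature falls northward at ``lat_gradient`` °C per degree,
    seasonality (the annual temperature half-range) grows with latitude,
    rainfall falls towards the north-west corner and concentrates in a
    July-centred monsoon peak, humidity tracks wetness, and a high plateau
    occupies part of the west, cooled by the atmospheric lapse rate.
    """

    south_mean_temp: float = 24.0     # °C annual mean at the southern edge
    lat_gradient: float = 0.7         # °C cooling per degree of latitude
    base_amplitude: float = 4.0       # °C seasonal half-range at the south edge
    amplitude_per_deg: float = 0.5    # extra half-range per degree northward
    diurnal_base: float = 8.0         # °C tmax-tmin in the wettest cells
    diurnal_dry_extra: float = 4.0    # additional range in the driest cells
    lapse_rate: float = 6.5           # °C per km of elevation
    annual_precip_wet: float = 1600.0 # mm/yr at the wettest (SE) corner
    annual_precip_dry: float = 60.0   # mm/yr at the driest (NW) corner
    monsoon_peak_weight: float = 3.0  # strength of the July rainfall peak
    rh_dry: float = 35.0              # mean RH (%) in the driest cells
    rh_wet: float = 85.0              # mean RH (%) in the wettest cells
    rh_diurnal: float = 8.0           # rh09 = mean + this, rh15 = mean - this
    plateau_height: float = 4200.0    # m, the western high plateau
    base_elevation: float = 300.0     # m elsewhere
    noise_sigma_cells: float = 2.0    # smoothing length of the random fields
    temp_noise: float = 0.5           # °C std of the smooth temperature noise
    wet_noise: float = 0.05           # std of the smooth wetness noise
    future_dtmax: float = 1.0         # °C warming of monthly maxima
    future_dtmin: float = 1.2         # °C warming of monthly minima
    future_precip_factor: float = 1.05  # Jan-Sep precipitation multiplier


def _smooth_noise(rng: np.random.Generator, shape, sigma) -> np.ndarray:
    white = rng.standard_normal(shape)
    sm = gaussian_filter(white, sigma=sigma, mode="reflect")
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def generate_synthetic_region(spec: GridSpec, seed: int,
                              scenario: str = "current",
                              config: SyntheticConfig = SyntheticConfig()) -> ClimateGrid:
    """Deterministic synthetic climatology for a monsoon-gradient region.

    ``scenario='future'`` returns the same fields warmed by the configured
    deltas (tmax +1.0 °C, tmin +1.2 °C by default) with Jan–Sep
    precipitation scaled up and humidity left unchanged, mirroring a
    near-term GCM anomaly pattern where the humidity response is unknown.
    """
    if scenario not in ("current", "future"):
        raise ValueError(f"scenario must be 'current' or 'future', got {scenario!r}")
    c = config
    rng = np.random.default_rng(seed)
    nrows, ncols = spec.n_rows, spec.n_cols
    lon, lat = spec.cell_centers()
    # normalised coordinates: x east, y north
    x = ((lon - spec.lon_origin) / (spec.n_cols * spec.cell_size)).reshape(nrows, ncols)
    y = ((lat - spec.lat_origin) / (spec.n_rows * spec.cell_size)).reshape(nrows, ncols)
    lat2 = lat.reshape(nrows, ncols)

    t_noise = _smooth_noise(rng, (nrows, ncols), c.noise_sigma_cells) * c.temp_noise
    w_noise = _smooth_noise(rng, (nrows, ncols), c.noise_sigma_cells) * c.wet_noise
    e_noise = _smooth_noise(rng, (nrows, ncols), c.noise_sigma_cells)

    # elevation: low base with a smooth-edged high plateau in the west
    plateau = (1 / (1 + np.exp(-(0.35 - x) * 25))) * (1 / (1 + np.exp(-(y - 0.40) * 25))) \
        * (1 / (1 + np.exp(-(0.95 - y) * 25)))
    elevation = c.base_elevation + 100.0 * e_noise + c.plateau_height * plateau
    elevation = np.maximum(0.0, elevation)

    # wetness: 1 at the SE corner, falling to 0 at the NW corner
    dryness = np.clip(((1 - x) + y) / 2.0 + w_noise, 0.0, 1.0)
    wetness = 1.0 - dryness

    annual_mean = (c.south_mean_temp
                   - c.lat_gradient * (lat2 - spec.lat_origin)
                   - c.lapse_rate * elevation / 1000.0
                   + t_noise)
    amplitude = c.base_amplitude + c.amplitude_per_deg * (lat2 - spec.lat_origin)
    months = np.arange(12)
    # seasonal cycle peaking in July (month index 6)
    season = np.cos(2 * np.pi * (months - 6.5 + 0.5) / 12.0)
    tavg = annual_mean[..., None] + amplitude[..., None] * season

    diurnal = c.diurnal_base + c.diurnal_dry_extra * dryness
    tmax = tavg + diurnal[..., None] / 2.0
    tmin = tavg - diurnal[..., None] / 2.0

    annual_precip = c.annual_precip_dry + \
        (c.annual_precip_wet - c.annual_precip_dry) * wetness
    monsoon = 1.0 + c.monsoon_peak_weight * np.exp(-0.5 * ((months - 6.0) / 1.8) ** 2)
    month_share = monsoon / monsoon.sum()
    precip = annual_precip[..., None] * month_share

    rh_mean = c.rh_dry + (c.rh_wet - c.rh_dry) * wetness
    # slightly moister air in the rainy season
    rh_season = 5.0 * (month_share * 12.0 - 1.0) / (c.monsoon_peak_weight + 1.0)
    rh = rh_mean[..., None] + rh_season
    rh09 = np.clip(rh + c.rh_diurnal, 0.0, 100.0)
    rh15 = np.clip(rh - c.rh_diurnal, 0.0, 100.0)

    n = spec.n_cells
    grid = ClimateGrid(
        spec=spec,
        tmax=tmax.reshape(n, 12), tmin=tmin.reshape(n, 12),
        precip=precip.reshape(n, 12),
        rh09=rh09.reshape(n, 12), rh15=rh15.reshape(n, 12),
        elevation=elevation.reshape(n),
    )
    if scenario == "future":
        grid.tmax = grid.tmax + c.future_dtmax
        grid.tmin = grid.tmin + c.future_dtmin
        precip_f = grid.precip.copy()
        precip_f[:, 0:9] *= c.future_precip_factor
        grid.precip = precip_f
    return grid


# ---------------------------------------------------------------------------
# grid CSV I/O

def write_grid_csv(grid: ClimateGrid, path: Union[str, Path]) -> None:
    """Write a grid as long-format CSV (cell_id, lon, lat, variable, month, value).

    The grid spec, elevation and mask travel in '#'-prefixed header lines so
    the file round-trips bit-exactly through :func:`read_grid_csv`.
    """
    s = grid.spec
    lon, lat = s.cell_centers()
    frames = []
    for var in CLIMATE_VARS:
        a = getattr(grid, var)
        df = pd.DataFrame({
            "cell_id": np.repeat(np.arange(s.n_cells), 12),
            "lon": np.repeat(lon, 12),
            "lat": np.repeat(lat, 12),
            "variable": var,
            "month": np.tile(np.arange(1, 13), s.n_cells),
            "value": a.ravel(),
        })
        frames.append(df)
    body = pd.concat(frames, ignore_index=True)
    header = [
        f"# gridspec {s.lon_origin!r} {s.lat_origin!r} {s.cell_size!r} "
        f"{s.n_cols} {s.n_rows}",
        "# elevation " + (" ".join(repr(float(e)) for e in grid.elevation)
                          if grid.elevation is not None else "none"),
        "# mask " + "".join("1" if m else "0" for m in grid.mask),
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        body.to_csv(fh, index=False, float_format="%.17g")


def read_grid_csv(path: Union[str, Path]) -> ClimateGrid:
    """Read a grid written by :func:`write_grid_csv`."""
    header: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, rest = line[1:].strip().partition(" ")
            header[key] = rest
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        body = pd.read_csv(fh, float_precision="round_trip")
    if "gridspec" not in header:
        raise ValueError(f"{path}: missing '# gridspec' header")
    lon0, lat0, size, ncols, nrows = header["gridspec"].split()
    spec = GridSpec(float(lon0), float(lat0), float(size), int(ncols), int(nrows))
    arrays = {}
    for var in CLIMATE_VARS:
        sub = body[body["variable"] == var].sort_values(["cell_id", "month"])
        if len(sub) != spec.n_cells * 12:
            raise ValueError(f"{path}: variable {var} incomplete")
        arrays[var] = sub["value"].to_numpy().reshape(spec.n_cells, 12)
    elevation = None
    if header.get("elevation", "none") != "none":
        elevation = np.array([float(t) for t in header["elevation"].split()])
    mask = None
    if "mask" in header:
        mask = np.array([ch == "1" for ch in header["mask"]])
    return ClimateGrid(spec=spec, elevation=elevation, mask=mask, **arrays)
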