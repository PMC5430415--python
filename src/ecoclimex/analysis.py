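"""Suitability products derived from per-cell engine results.

Turns gridded Ecoclimatic Index (EI) values into favourability classes,
area summaries, limiting-factor masks, per-region impact indices,
current-vs-future EI differences and range shifts, and occurrence-record
validation.

Favourability classes follow the standard EI banding: unfavourable
(EI = 0), marginally favourable (0 < EI ≤ 10), favourable (10 < EI ≤ 20)
and highly favourable (EI > 20).  The boundary value EI = 20 belongs to
the favourable class.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .climate import ClimateGrid, GridSpec
from .engine import LIMITING_FLAGS, run_cells
from .params import SpeciesParams

logger = logging.getLogger(__name__)

__all__ = [
    "CLASS_NAMES",
    "SuitabilityGrid",
    "OccurrenceRecord",
    "classify_ei",
    "run_suitability",
    "area_summary",
    "limiting_factor_map",
    "impact_index",
    "ei_difference",
    "range_shift",
    "validate_occurrences",
    "make_synthetic_occurrences",
    "read_occurrence_csv",
    "write_occurrence_csv",
]

CLASS_NAMES = ("unfavourable", "marginal", "favourable", "highly_favourable")
_SUITABLE = frozenset(CLASS_NAMES[1:])


@dataclass(frozen=True)
class OccurrenceRecord:
    """A species occurrence point (lon/lat) with its provenance and role."""

    lon: float
    lat: float
    source: str = "literature"   # CABI | literature
    role: str = "modelling"      # modelling | validation

    def __post_init__(self):
        if not (-180 <= self.lon <= 180) or not (-90 <= self.lat <= 90):
            raise ValueError("occurrence coordinates out of range")
        if self.role not in ("modelling", "validation"):
            raise ValueError(f"unknown role {self.role!r}")


@dataclass
class SuitabilityGrid:
    """Gridded EI with favourability classes, limiting flags and cell areas.

    ``ei`` and ``cell_area`` are ``(n_cells,)`` arrays; ``classes`` holds
    one of :data:`CLASS_NAMES` per cell; ``flags`` maps each limiting
    condition name to a boolean mask.  ``results`` keeps the full engine
    output dict for downstream diagnostics.
    """

    spec: GridSpec
    ei: np.ndarray
    classes: np.ndarray
    flags: dict[str, np.ndarray]
    cell_area: np.ndarray
    mask: np.ndarray
    results: Optional[dict[str, np.ndarray]] = None


def classify_ei(ei) -> np.ndarray:
    """Assign favourability classes to EI values (scalar or array).

    0 → unfavourable; (0, 10] → marginal; (10, 20] → favourable;
    > 20 → highly favourable.  Values outside [0, 100] are rejected.
    """
    a = np.asarray(ei, dtype=float)
    if np.any((a < 0) | (a > 100) | ~np.isfinite(a)):
        raise ValueError("EI values must lie in [0, 100]")
    out = np.select(
        [a == 0, a <= 10, a <= 20],
        [CLASS_NAMES[0], CLASS_NAMES[1], CLASS_NAMES[2]],
        default=CLASS_NAMES[3],
    )
    return out if out.shape else out[()]


def run_suitability(grid: ClimateGrid, p: SpeciesParams, **engine_kwargs) -> SuitabilityGrid:
    """Run the weekly engine over every cell of a climate grid and classify.

    Masked cells get EI = 0 and the unfavourable class but are excluded
    from all area summaries downstream.
    """
    bad = grid.violations()
    if bad:
        raise ValueError("invalid climate grid: " + "; ".join(bad))
    r = run_cells(grid.tmax, grid.tmin, grid.precip, grid.rh09, grid.rh15,
                  p, **engine_kwargs)
    ei = np.where(grid.mask, r["ei"], 0.0)
    flags = {f: r[f] & grid.mask for f in LIMITING_FLAGS}
    return SuitabilityGrid(
        spec=grid.spec, ei=ei, classes=classify_ei(ei), flags=flags,
        cell_area=grid.spec.cell_areas(), mask=grid.mask.copy(), results=r,
    )


def area_summary(sg: SuitabilityGrid,
                 region: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Per-class areas (km²) and shares of the region and of the potential
    distribution (all classes above unfavourable).

    ``region`` is an optional boolean cell mask restricting the summary.
    Percentages are NaN when their denominator is zero.
    """
    sel = sg.mask if region is None else (sg.mask & np.asarray(region, dtype=bool))
    rows = []
    total = float(sg.cell_area[sel].sum())
    potential = float(sg.cell_area[sel & (sg.classes != CLASS_NAMES[0])].sum())
    for cls in CLASS_NAMES:
        area = float(sg.cell_area[sel & (sg.classes == cls)].sum())
        pct_region = 100.0 * area / total if total > 0 else math.nan
        if cls == CLASS_NAMES[0]:
            pct_pot = math.nan
        else:
            pct_pot = 100.0 * area / potential if potential > 0 else math.nan
        rows.append({"class": cls, "area_km2": area,
                     "pct_of_region": pct_region,
                     "pct_of_potential": pct_pot})
    rows.append({"class": "potential_total", "area_km2": potential,
                 "pct_of_region": 100.0 * potential / total if total > 0 else math.nan,
                 "pct_of_potential": 100.0 if potential > 0 else math.nan})
    return pd.DataFrame(rows)


def limiting_factor_map(sg: SuitabilityGrid) -> dict[str, np.ndarray]:
    """Boolean cell mask per zero-EI condition; a cell may appear in several."""
    return {f: m.copy() for f, m in sg.flags.items()}


def impact_index(affected: np.ndarray, region: np.ndarray,
                 cell_area: np.ndarray) -> int:
    """0–10 integer impact of a limiting condition in a region.

    The index is the affected *area* fraction of the region scaled to ten
    and rounded half-up.
    """
    region = np.asarray(region, dtype=bool)
    if not region.any():
        raise ValueError("region is empty")
    affected = np.asarray(affected, dtype=bool) & region
    frac = float(cell_area[affected].sum()) / float(cell_area[region].sum())
    return int(math.floor(10.0 * frac + 0.5))


def ei_difference(current: SuitabilityGrid, future: SuitabilityGrid
                  ) -> tuple[np.ndarray, dict[str, float]]:
    """Per-cell ΔEI (future − current) and its summary statistics."""
    if current.spec != future.spec:
        raise ValueError("grids must share one GridSpec")
    delta = future.ei - current.ei
    m = current.mask & future.mask
    summary = {
        "max_increase": float(delta[m].max()),
        "max_decrease": float(delta[m].min()),
        "mean": float(delta[m].mean()),
    }
    return delta, summary


def range_shift(current: SuitabilityGrid, future: SuitabilityGrid, cls: str,
                region: Optional[np.ndarray] = None) -> Optional[float]:
    """Northward shift (degrees latitude) of a class's area-weighted centroid.

    Returns None when the class is absent from either scenario within the
    region (the shift is undefined there, not zero).
    """
    if current.spec != future.spec:
        raise ValueError("grids must share one GridSpec")
    if cls not in CLASS_NAMES:
        raise ValueError(f"unknown class {cls!r}")
    _, lat = current.spec.cell_centers()
    sel = current.mask & future.mask
    if region is not None:
        sel = sel & np.asarray(region, dtype=bool)
    cents = []
    for sg in (current, future):
        in_cls = sel & (sg.classes == cls)
        w = sg.cell_area[in_cls]
        if w.sum() == 0:
            return None
        cents.append(float(np.average(lat[in_cls], weights=w)))
    return cents[1] - cents[0]


def validate_occurrences(points: Sequence[OccurrenceRecord],
                         sg: SuitabilityGrid) -> tuple[float, pd.DataFrame]:
    """Fraction (%) of validation occurrences that fall in suitable cells.

    A point is suitable when its containing cell's class is anything other
    than unfavourable.  Points outside the grid (or in masked cells) are
    excluded from the denominator with a logged warning.  Returns the
    percentage and a per-point table (lon, lat, cell, ei, class, suitable).
    """
    val = [pt for pt in points if pt.role == "validation"]
    if not val:
        raise ValueError("no validation points supplied")
    lon = np.array([pt.lon for pt in val])
    lat = np.array([pt.lat for pt in val])
    idx = sg.spec.cell_index(lon, lat)
    usable = idx >= 0
    usable[usable] &= sg.mask[idx[usable]]
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.warning("validate_occurrences: %d point(s) outside the grid "
                       "extent excluded", n_dropped)
    if not usable.any():
        raise ValueError("no validation points fall inside the grid")
    rows = []
    for i, pt in enumerate(val):
        if usable[i]:
            cell = int(idx[i])
            ei = float(sg.ei[cell])
            cls = str(sg.classes[cell])
            suitable = cls in _SUITABLE
        else:
            cell, ei, cls, suitable = -1, math.nan, "outside", False
        rows.append({"lon": pt.lon, "lat": pt.lat, "cell": cell, "ei": ei,
                     "class": cls, "suitable": suitable,
                     "usable": bool(usable[i])})
    table = pd.DataFrame(rows)
    pct = 100.0 * table.loc[table.usable, "suitable"].mean()
    return float(pct), table


def make_synthetic_occurrences(sg: SuitabilityGrid, seed: int,
                               n_modelling: int = 53, n_validation: int = 20,
                               n_unsuitable: int = 1) -> list[OccurrenceRecord]:
    """Construct a synthetic occurrence set from a suitability grid.

    Emulates a typical validation design: ``n_validation`` points of which
    ``n_unsuitable`` are placed in unfavourable cells (so a 20-point set
    with one unsuitable point validates at 95%), the rest plus
    ``n_modelling`` modelling points in suitable cells, all jittered
    uniformly within their cells.  Synthetic stand-in for field records.
    """
    rng = np.random.default_rng(seed)
    lon, lat = sg.spec.cell_centers()
    good = np.nonzero(sg.mask & (sg.classes != CLASS_NAMES[0]))[0]
    bad = np.nonzero(sg.mask & (sg.classes == CLASS_NAMES[0]))[0]
    if len(good) == 0:
        raise ValueError("grid has no suitable cells")
    if n_unsuitable > 0 and len(bad) == 0:
        raise ValueError("grid has no unfavourable cells to place points in")

    def sample(cells, n, role):
        chosen = rng.choice(cells, size=n, replace=len(cells) < n)
        jitter = (rng.random((n, 2)) - 0.5) * sg.spec.cell_size * 0.9
        return [OccurrenceRecord(lon=float(lon[c] + jx), lat=float(lat[c] + jy),
                                 source="literature", role=role)
                for c, (jx, jy) in zip(chosen, jitter)]

    pts = sample(good, n_modelling, "modelling")
    pts += sample(good, n_validation - n_unsuitable, "validation")
    if n_unsuitable:
        pts += sample(bad, n_unsuitable, "validation")
    return pts


def read_occurrence_csv(path: Union[str, Path]) -> list[OccurrenceRecord]:
    """Read occurrences from a CSV with columns lon, lat, source, role."""
    df = pd.read_csv(path)
    missing = [c for c in ("lon", "lat", "source", "role") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return [OccurrenceRecord(lon=float(r.lon), lat=float(r.lat),
                             source=str(r.source), role=str(r.role))
            for r in df.itertuples()]


def write_occurrence_csv(points: Sequence[OccurrenceRecord],
                         path: Union[str, Path]) -> None:
    pd.DataFrame([{"lon": p.lon, "lat": p.lat, "source": p.source,
                   "role": p.role} for p in points]).to_csv(path, index=False)
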