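"""One-at-a-time parameter sensitivity of mean EI over a climate grid.

Each sweep perturbs a single parameter, reruns the full engine over the
grid, and records the mean EI over unmasked cells (zeros included) next
to the baseline value.  Perturbed parameter sets that violate the
species-parameter invariants are skipped with a logged reason rather than
silently distorting the sweep.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .analysis import run_suitability
from .climate import ClimateGrid
from .params import SpeciesParams, validate_params

logger = logging.getLogger(__name__)

__all__ = ["SWEEPABLE", "SensitivityRecord", "one_at_a_time", "sweep_all",
           "default_plan"]

#: Parameters exposed to the sweep (lower-case field names).
SWEEPABLE = ("dv0", "dv1", "dv2", "dv3", "ttcs", "pdd",
             "sm0", "sm1", "sm2", "sm3")


@dataclass(frozen=True)
class SensitivityRecord:
    parameter: str
    perturbed_value: float
    mean_ei: float
    delta_mean_ei: float


def _mean_ei(grid: ClimateGrid, p: SpeciesParams) -> float:
    sg = run_suitability(grid, p)
    return float(sg.ei[sg.mask].mean())


def one_at_a_time(base: SpeciesParams, climate: ClimateGrid, parameter: str,
                  values: Sequence[float]) -> list[SensitivityRecord]:
    """Sweep one parameter over the given values.

    The baseline mean EI is computed with ``base`` unchanged; each record
    carries the perturbed mean EI and its delta against that baseline.
    """
    parameter = parameter.lower()
    if parameter not in SWEEPABLE:
        raise ValueError(f"unknown sweep parameter {parameter!r}; "
                         f"choose from {SWEEPABLE}")
    baseline = _mean_ei(climate, base)
    records = []
    for v in values:
        p = base.replace(**{parameter: float(v)})
        bad = validate_params(p)
        if bad:
            logger.warning("skipping %s=%s: %s", parameter, v, "; ".join(bad))
            continue
        m = _mean_ei(climate, p)
        records.append(SensitivityRecord(parameter=parameter,
                                         perturbed_value=float(v),
                                         mean_ei=m,
                                         delta_mean_ei=m - baseline))
    return records


def default_plan(base: SpeciesParams,
                 fractions: Sequence[float] = (-0.10, -0.05, 0.0, 0.05, 0.10)
                 ) -> dict[str, list[float]]:
    """±5% and ±10% perturbations of each sweepable parameter's fitted value.

    Parameters whose fitted value is 0 are swept additively by the same
    fractions of 1 unit so the sweep is never degenerate.
    """
    plan = {}
    for name in SWEEPABLE:
        v0 = getattr(base, name)
        if v0 == 0:
            plan[name] = [f for f in fractions]
        else:
            plan[name] = [v0 * (1 + f) for f in fractions]
    return plan


def sweep_all(base: SpeciesParams, climate: ClimateGrid,
              plan: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Run :func:`one_at_a_time` for every parameter in the plan.

    Records are ordered by parameter name then perturbed value, so
    repeated runs on the same grid produce identical tables.
    """
    if not plan:
        raise ValueError("empty sensitivity plan")
    rows = []
    for parameter in sorted(plan):
        recs = one_at_a_time(base, climate, parameter, sorted(plan[parameter]))
        rows.extend(vars(r) for r in recs)
    return pd.DataFrame(rows, columns=["parameter", "perturbed_value",
                                       "mean_ei", "delta_mean_ei"])
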