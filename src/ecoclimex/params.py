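"""Species parameter set for the ecoclimatic suitability model.

The model is driven by 17 parameters grouped into a temperature response
(DV0–DV3), a soil-moisture response (SM0–SM3), four stress threshold/rate
pairs (cold, heat, dry, wet) and a degree-day requirement (PDD) for the
completion of one generation.  Stress *rates* are stored with the signs in
which they are conventionally printed (cold and dry rates negative); the
engine takes magnitudes at the point of use, so the sign convention never
affects accumulation.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Union

__all__ = [
    "SpeciesParams",
    "default_fornicatus_params",
    "wet_tropical_template",
    "validate_params",
    "write_params",
    "read_params",
]

#: Canonical field order and the mnemonic used in parameter files.
PARAM_KEYS = {
    "dv0": "DV0",
    "dv1": "DV1",
    "dv2": "DV2",
    "dv3": "DV3",
    "sm0": "SM0",
    "sm1": "SM1",
    "sm2": "SM2",
    "sm3": "SM3",
    "ttcs": "TTCS",
    "thcs": "THCS",
    "tths": "TTHS",
    "thhs": "THHS",
    "smds": "SMDS",
    "hds": "HDS",
    "smws": "SMWS",
    "hws": "HWS",
    "pdd": "PDD",
}
_MNEMONIC_TO_FIELD = {v: k for k, v in PARAM_KEYS.items()}


@dataclass(frozen=True)
class SpeciesParams:
    """Parameter set of the weekly growth/stress model.

    Attributes
    ----------
    dv0, dv1, dv2, dv3 : float
        Temperature response trapezoid, °C: growth is zero at/below ``dv0``,
        optimal on ``[dv1, dv2]`` and zero at/above ``dv3``.
    sm0, sm1, sm2, sm3 : float
        Soil-moisture response trapezoid, as a fraction of bucket capacity
        (values above 1 express waterlogging).
    ttcs, thcs : float
        Cold-stress temperature threshold (°C) and weekly rate (week⁻¹,
        stored ≤ 0 by convention).
    tths, thhs : float
        Heat-stress temperature threshold (°C) and weekly rate (week⁻¹, ≥ 0).
    smds, hds : float
        Dry-stress soil-moisture threshold (fraction) and weekly rate
        (week⁻¹, stored ≤ 0 by convention).
    smws, hws : float
        Wet-stress soil-moisture threshold (fraction) and weekly rate
        (week⁻¹, ≥ 0).
    pdd : float
        Degree-days above ``dv0`` required to complete one generation.
    pdd_enabled : bool
        When False the generation requirement is ignored (used by the
        wet-tropical template, which prints PDD as 0 meaning "no
        constraint").
    """

    dv0: float
    dv1: float
    dv2: float
    dv3: float
    sm0: float
    sm1: float
    sm2: float
    sm3: float
    ttcs: float
    thcs: float
    tths: float
    thhs: float
    smds: float
    hds: float
    smws: float
    hws: float
    pdd: float
    pdd_enabled: bool = True

    def replace(self, **changes) -> "SpeciesParams":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)


def default_fornicatus_params() -> SpeciesParams:
    """Fitted parameter set for *Euwallacea fornicatus*.

    Temperature thresholds come from rearing studies (immature stages do
    not survive below 15 °C; activity is optimal between 26 and 35 °C);
    the 373 degree-day generation requirement is the sum of egg-to-adult
    development (≈237 DD) and the preoviposition period (≈136 DD).
    """
    return SpeciesParams(
        dv0=15.0, dv1=26.0, dv2=35.0, dv3=40.0,
        sm0=0.05, sm1=0.3, sm2=1.0, sm3=2.5,
        ttcs=-10.0, thcs=-0.005,
        tths=42.0, thhs=0.0002,
        smds=0.05, hds=-0.001,
        smws=2.5, hws=0.005,
        pdd=373.0, pdd_enabled=True,
    )


def wet_tropical_template() -> SpeciesParams:
    """Wet-tropical template used as the starting point for fitting.

    The template prints its dry-stress rate as +0.01 and PDD as 0; the
    rate is stored sign-normalised (≤ 0) and PDD = 0 is represented by
    disabling the generation requirement rather than by the number 0.
    """
    return SpeciesParams(
        dv0=15.0, dv1=28.0, dv2=33.0, dv3=36.0,
        sm0=0.35, sm1=0.7, sm2=1.5, sm3=2.5,
        ttcs=2.0, thcs=0.0,
        tths=37.0, thhs=0.0002,
        smds=0.25, hds=-0.01,
        smws=2.5, hws=0.002,
        pdd=0.0, pdd_enabled=False,
    )


def validate_params(p: SpeciesParams) -> list[str]:
    """Check the parameter invariants; return a description per violation.

    An empty list means the parameter set is valid.  Violations name the
    offending fields and the relation they break.
    """
    v: list[str] = []
    for name in PARAM_KEYS:
        x = getattr(p, name)
        if not math.isfinite(x):
            v.append(f"{name} is not finite")
    if v:
        return v
    if not p.dv0 < p.dv1:
        v.append(f"dv0<dv1 violated: dv0={p.dv0} dv1={p.dv1}")
    if not p.dv1 <= p.dv2:
        v.append(f"dv1<=dv2 violated: dv1={p.dv1} dv2={p.dv2}")
    if not p.dv2 < p.dv3:
        v.append(f"dv2<dv3 violated: dv2={p.dv2} dv3={p.dv3}")
    if not p.sm0 < p.sm1:
        v.append(f"sm0<sm1 violated: sm0={p.sm0} sm1={p.sm1}")
    if not p.sm1 <= p.sm2:
        v.append(f"sm1<=sm2 violated: sm1={p.sm1} sm2={p.sm2}")
    if not p.sm2 <= p.sm3:
        v.append(f"sm2<=sm3 violated: sm2={p.sm2} sm3={p.sm3}")
    if p.pdd_enabled and not p.pdd > 0:
        v.append(f"pdd>0 violated while generation check enabled: pdd={p.pdd}")
    if p.thcs > 0:
        v.append(f"thcs<=0 violated: thcs={p.thcs}")
    if p.hds > 0:
        v.append(f"hds<=0 violated: hds={p.hds}")
    if p.thhs < 0:
        v.append(f"thhs>=0 violated: thhs={p.thhs}")
    if p.hws < 0:
        v.append(f"hws>=0 violated: hws={p.hws}")
    return v


def write_params(p: SpeciesParams, path: Union[str, Path]) -> None:
    """Write a parameter set as a flat ``KEY = value`` text config.

    Floats are written with ``repr`` so the round-trip is lossless.
    """
    lines = []
    for field, key in PARAM_KEYS.items():
        lines.append(f"{key} = {getattr(p, field)!r}")
    lines.append(f"PDD_ENABLED = {int(p.pdd_enabled)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_params(path: Union[str, Path]) -> SpeciesParams:
    """Parse a flat key-value parameter file written by :func:`write_params`.

    Unknown keys raise ``ValueError``; missing keys fall back to the
    fitted defaults so partial overrides are convenient.
    """
    values: dict[str, float] = {}
    pdd_enabled = True
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'KEY = value', got {raw!r}")
        key, _, val = line.partition("=")
        key = key.strip().upper()
        val = val.strip()
        if key == "PDD_ENABLED":
            pdd_enabled = bool(int(val))
            continue
        if key not in _MNEMONIC_TO_FIELD:
            raise ValueError(f"{path}:{lineno}: unknown parameter {key!r}")
        try:
            values[_MNEMONIC_TO_FIELD[key]] = float(val)
        except ValueError as e:
            raise ValueError(f"{path}:{lineno}: unparseable number {val!r}") from e
    base = dataclasses.asdict(default_fornicatus_params())
    base.update(values)
    base["pdd_enabled"] = pdd_enabled
    return SpeciesParams(**base)
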