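"""Growth rates between two observation dates.

For any measured quantity v (image-based whole-plant area, dry weight,
shoot length, ...) observed at times t₁ < t₂ (days):

    AGR = (v₂ − v₁) / (t₂ − t₁)                 units · day⁻¹
    RGR = (ln v₂ − ln v₁) / (t₂ − t₁)           day⁻¹
    CGR = (v₂ − v₁) / (P · (t₂ − t₁))           units · m⁻² · day⁻¹

with P the land/spacing area in m².  P defaults to 1, under which CGR
coincides with AGR; the 20 cm × 15 cm pot spacing (0.03 m²) is available
as an option.  Rates are usually computed from genotype means of v at each
date; replicate-level observations work identically.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import pandas as pd

from .errors import DomainError, TimeOrderError, ValidationError
from .io import TraitTable


class Quantity(str, enum.Enum):
    WPA_I = "wpa_i"
    WPA_S = "wpa_s"
    SHOOT_LENGTH = "shoot_length"
    ROOT_LENGTH = "root_length"
    SHOOT_DRY_WEIGHT = "shoot_dry_weight"
    ROOT_DRY_WEIGHT = "root_dry_weight"
    GENERIC = "generic"


@dataclass(frozen=True)
class GrowthObservation:
    """Paired measurements of one quantity at two times."""

    v1: float
    v2: float
    t1: float
    t2: float
    quantity: Quantity = Quantity.GENERIC
    spacing_p: float = 1.0  # m²
    units: str = ""

    def __post_init__(self):
        if not (self.t2 > self.t1):
            raise TimeOrderError(f"t2 ({self.t2}) must exceed t1 ({self.t1})")
        if not (self.spacing_p > 0):
            raise ValidationError(f"spacing_p must be positive, got {self.spacing_p}")
        object.__setattr__(self, "quantity", Quantity(self.quantity))

    @property
    def dt(self) -> float:
        return self.t2 - self.t1


@dataclass(frozen=True)
class GrowthRates:
    agr: float
    rgr: float
    cgr: float


def absolute_growth_rate(obs: GrowthObservation) -> float:
    """AGR = (v₂ − v₁)/(t₂ − t₁)."""
    return (obs.v2 - obs.v1) / obs.dt


def relative_growth_rate(obs: GrowthObservation) -> float:
    """RGR = (ln v₂ − ln v₁)/(t₂ − t₁); requires strictly positive values."""
    if not (obs.v1 > 0 and obs.v2 > 0):
        raise DomainError(
            f"RGR needs positive values, got v1={obs.v1}, v2={obs.v2}"
        )
    return (math.log(obs.v2) - math.log(obs.v1)) / obs.dt


def crop_growth_rate(obs: GrowthObservation) -> float:
    """CGR = (v₂ − v₁)/(P·(t₂ − t₁)); equals AGR when P = 1."""
    return (obs.v2 - obs.v1) / (obs.spacing_p * obs.dt)


def growth_rates(obs: GrowthObservation) -> GrowthRates:
    """All three rates for one observation pair."""
    return GrowthRates(
        agr=absolute_growth_rate(obs),
        rgr=relative_growth_rate(obs),
        cgr=crop_growth_rate(obs),
    )


def growth_rates_between_tables(
    table1: TraitTable,
    table2: TraitTable,
    trait: str,
    spacing_p: float = 1.0,
) -> pd.DataFrame:
    """Per-genotype AGR/RGR/CGR for one trait between two dated tables.

    Genotypes missing from either table, or with a missing/non-positive
    value at either date (RGR undefined), get NaN rates for the affected
    statistics.
    """
    if not (table2.das > table1.das):
        raise TimeOrderError(
            f"second table must be later: das {table1.das} -> {table2.das}"
        )
    v1 = table1.column(trait)
    v2 = table2.column(trait)
    rows = []
    for genotype in table1.genotypes:
        if genotype not in v2.index:
            continue
        a, b = float(v1[genotype]), float(v2[genotype])
        obs = None
        if not (pd.isna(a) or pd.isna(b)):
            obs = GrowthObservation(
                v1=a, v2=b, t1=table1.das, t2=table2.das, spacing_p=spacing_p
            )
        rows.append(
            {
                "genotype": genotype,
                "agr": absolute_growth_rate(obs) if obs else float("nan"),
                "rgr": (
                    relative_growth_rate(obs)
                    if obs and a > 0 and b > 0
                    else float("nan")
                ),
                "cgr": crop_growth_rate(obs) if obs else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("genotype")
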