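"""Predator energetics arithmetic: from a daily caloric requirement to the
annual prey biomass a subpopulation would consume, and its share of
regional prey biomass.

Every step returns exact (unrounded) values; :func:`consumption_chain`
additionally carries a ``display`` column reproducing the rounding
convention of the narrative it models: mass quantities are *truncated* to
the printed precision and each step chains on the previous step's truncated
display value, while the final percentage is rounded to the nearest whole
number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "EnergeticsParams",
    "daily_intake_mass",
    "population_annual_fat",
    "prey_biomass_required",
    "regional_biomass",
    "fraction_of_regional",
    "truncate_to",
    "consumption_chain",
]

DAYS_PER_YEAR = 365.0


def _require_positive(**kwargs) -> None:
    for name, value in kwargs.items():
        if not (value > 0):
            raise ValueError(f"{name} must be > 0, got {value}")


def _require_fraction(**kwargs) -> None:
    for name, value in kwargs.items():
        if not (0.0 < value <= 1.0):
            raise ValueError(f"{name} must be in (0, 1], got {value}")


@dataclass(frozen=True)
class EnergeticsParams:
    """Inputs to the consumption chain (defaults mirror the worked example)."""

    daily_kcal: float = 12_000.0
    kcal_per_g_fat: float = 9.0
    kcal_per_g_protein: float = 4.0
    fat_fraction: float = 0.8
    n_bears: int = 900
    diet_fraction: float = 0.17
    prey_lipid_fraction: float = 0.10
    density_kg_km2: float = 280.0
    area_km2: float = 50_000.0

    def __post_init__(self):
        _require_positive(
            daily_kcal=self.daily_kcal,
            kcal_per_g_fat=self.kcal_per_g_fat,
            kcal_per_g_protein=self.kcal_per_g_protein,
            n_bears=self.n_bears,
            density_kg_km2=self.density_kg_km2,
            area_km2=self.area_km2,
        )
        _require_fraction(
            fat_fraction=self.fat_fraction,
            diet_fraction=self.diet_fraction,
            prey_lipid_fraction=self.prey_lipid_fraction,
        )


def daily_intake_mass(
    daily_kcal: float,
    fat_fraction: float,
    kcal_per_g_fat: float = 9.0,
    kcal_per_g_protein: float = 4.0,
) -> tuple[float, float]:
    """(kg fat/day, kg protein/day) meeting ``daily_kcal`` at a fat:protein split."""
    _require_positive(daily_kcal=daily_kcal, kcal_per_g_fat=kcal_per_g_fat,
                      kcal_per_g_protein=kcal_per_g_protein)
    if not (0.0 <= fat_fraction <= 1.0):
        raise ValueError(f"fat_fraction must be in [0, 1], got {fat_fraction}")
    fat_kg = fat_fraction * daily_kcal / kcal_per_g_fat / 1000.0
    protein_kg = (1.0 - fat_fraction) * daily_kcal / kcal_per_g_protein / 1000.0
    return fat_kg, protein_kg


def population_annual_fat(kg_fat_per_bear_day: float, n_bears: float) -> float:
    """Thousand kg of fat per year for the whole subpopulation."""
    if kg_fat_per_bear_day < 0 or n_bears < 0:
        raise ValueError("inputs must be nonnegative")
    return kg_fat_per_bear_day * n_bears * DAYS_PER_YEAR / 1000.0


def prey_biomass_required(
    annual_fat_thousand_kg: float,
    diet_fraction: float,
    prey_lipid_fraction: float,
) -> float:
    """Thousand kg of the focal prey consumed per year."""
    _require_fraction(diet_fraction=diet_fraction,
                      prey_lipid_fraction=prey_lipid_fraction)
    if annual_fat_thousand_kg < 0:
        raise ValueError("annual fat must be nonnegative")
    return annual_fat_thousand_kg * diet_fraction / prey_lipid_fraction


def regional_biomass(density_kg_km2: float, area_km2: float) -> float:
    """Regional prey biomass in kg from a density and an area."""
    _require_positive(density_kg_km2=density_kg_km2, area_km2=area_km2)
    return density_kg_km2 * area_km2


def fraction_of_regional(consumed_kg: float, regional_kg: float) -> float:
    """Consumed biomass as a percentage of regional biomass."""
    _require_positive(regional_kg=regional_kg)
    if consumed_kg < 0:
        raise ValueError("consumed biomass must be nonnegative")
    return 100.0 * consumed_kg / regional_kg


def truncate_to(value: float, decimals: int = 0) -> float:
    """Truncate toward zero at ``decimals`` decimal places.

    Scaled values are pre-rounded at 1e-9 so binary float artifacts
    (e.g. ``55 / 0.1 == 549.999...``) do not flip the truncation.
    """
    scale = 10.0**decimals
    return math.trunc(round(value * scale, 9)) / scale


def consumption_chain(params: EnergeticsParams = EnergeticsParams()) -> pd.DataFrame:
    """Run the whole consumption chain.

    Returns a step table with ``exact`` (unrounded, computed from exact
    upstream values) and ``display`` (truncated-and-chained) columns so the
    narrative rounding convention is transparent rather than baked in.
    """
    p = params
    fat_only, _ = daily_intake_mass(p.daily_kcal, 1.0, p.kcal_per_g_fat, p.kcal_per_g_protein)
    _, protein_only = daily_intake_mass(p.daily_kcal, 0.0, p.kcal_per_g_fat, p.kcal_per_g_protein)
    fat_split, protein_split = daily_intake_mass(
        p.daily_kcal, p.fat_fraction, p.kcal_per_g_fat, p.kcal_per_g_protein
    )

    d_fat_only = truncate_to(fat_only, 1)
    d_protein_only = truncate_to(protein_only, 1)
    d_fat_split = truncate_to(fat_split, 1)
    d_protein_split = truncate_to(protein_split, 1)

    annual_fat = population_annual_fat(fat_split, p.n_bears)
    d_annual_fat = truncate_to(population_annual_fat(d_fat_split, p.n_bears), 0)

    seabird_fat = prey_biomass_required(annual_fat, p.diet_fraction, 1.0)
    d_seabird_fat = truncate_to(d_annual_fat * p.diet_fraction, 0)

    prey_mass = prey_biomass_required(annual_fat, p.diet_fraction, p.prey_lipid_fraction)
    d_prey_mass = truncate_to(d_seabird_fat / p.prey_lipid_fraction, 0)

    regional = regional_biomass(p.density_kg_km2, p.area_km2)
    pct = fraction_of_regional(prey_mass * 1000.0, regional)
    d_pct = round(fraction_of_regional(d_prey_mass * 1000.0, regional))

    rows = [
        ("fat_only_kg_day", "kg fat/day at 100% fat", fat_only, d_fat_only),
        ("protein_only_kg_day", "kg protein/day at 100% protein", protein_only, d_protein_only),
        ("fat_split_kg_day", "kg fat/day at the fat:protein split", fat_split, d_fat_split),
        ("protein_split_kg_day", "kg protein/day at the fat:protein split", protein_split, d_protein_split),
        ("annual_fat_thousand_kg", "thousand kg fat/year, subpopulation", annual_fat, d_annual_fat),
        ("prey_fat_thousand_kg", "thousand kg fat/year from focal prey", seabird_fat, d_seabird_fat),
        ("prey_biomass_thousand_kg", "thousand kg prey/year consumed", prey_mass, d_prey_mass),
        ("regional_biomass_kg", "regional prey biomass, kg", regional, regional),
        ("percent_of_regional", "% of regional biomass consumed", pct, d_pct),
    ]
    return pd.DataFrame(rows, columns=["step", "description", "exact", "display"]).set_index("step")
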