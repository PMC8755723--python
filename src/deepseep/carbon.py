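"""Annual carbon mass balance of a CO2-driven cold-water geyser.

The budget compares the carbon erupted per year as dissolved inorganic
species (CO2 and bicarbonate) with the carbon bound in erupted microbial
cells, yielding the percentage of degassing mantle carbon fixed into biomass.
Eruption count and concentrations are free inputs; the intracellular carbon
content defaults to 14 fg per cell (the standard subsurface estimate) and the
eruption season to ~210 days (1 April - 31 October).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

#: molar carbon mass fractions
C_FRACTION_CO2 = 12.011 / 44.009
C_FRACTION_HCO3 = 12.011 / 61.016


def _check_positive(**values: float) -> None:
    for name, v in values.items():
        if not math.isfinite(v) or v < 0:
            raise ValueError(f"parameter '{name}' must be finite and >= 0")


@dataclass(frozen=True)
class BudgetInputs:
    co2_mg_per_l: float
    hco3_mg_per_l: float
    cells_per_ml: float
    eruption_volume_m3: float
    eruptions_per_day: float = 12.0      # one eruption roughly every two hours
    season_days: float = 210.0
    fg_c_per_cell: float = 14.0

    def __post_init__(self) -> None:
        _check_positive(**asdict(self))


def tubing_volume(radius_m: float, length_m: float) -> float:
    """Cylinder volume pi * r^2 * L in cubic metres."""
    if radius_m <= 0 or length_m <= 0:
        raise ValueError("radius_m and length_m must be positive")
    return math.pi * radius_m ** 2 * length_m


def annual_eruptions(season_days: float, eruptions_per_day: float) -> float:
    _check_positive(season_days=season_days, eruptions_per_day=eruptions_per_day)
    return season_days * eruptions_per_day


def cell_carbon(
    cells_per_ml: float,
    fg_c_per_cell: float,
    eruption_volume_m3: float,
    eruptions_per_year: float,
) -> float:
    """Cell-bound carbon erupted per year, in grams.

    cells/ml x 1e6 ml/m3 x m3/eruption x eruptions/yr x fg/cell x 1e-15 g/fg.
    """
    _check_positive(cells_per_ml=cells_per_ml, fg_c_per_cell=fg_c_per_cell,
                    eruption_volume_m3=eruption_volume_m3,
                    eruptions_per_year=eruptions_per_year)
    return (cells_per_ml * 1e6 * eruption_volume_m3 * eruptions_per_year
            * fg_c_per_cell * 1e-15)


def erupted_carbon(
    co2_mg_per_l: float,
    hco3_mg_per_l: float,
    eruption_volume_m3: float,
    eruptions_per_year: float,
) -> float:
    """Inorganic carbon erupted per year, in kg.

    1 mg/L = 1 g/m3; the carbon shares of CO2 and HCO3- are 12.011/44.009 and
    12.011/61.016 by molar mass.
    """
    _check_positive(co2_mg_per_l=co2_mg_per_l, hco3_mg_per_l=hco3_mg_per_l,
                    eruption_volume_m3=eruption_volume_m3,
                    eruptions_per_year=eruptions_per_year)
    g_per_m3 = co2_mg_per_l * C_FRACTION_CO2 + hco3_mg_per_l * C_FRACTION_HCO3
    return eruption_volume_m3 * eruptions_per_year * g_per_m3 * 1e-3


def fixed_fraction(cell_c_g_per_yr: float, erupted_c_kg_per_yr: float) -> float:
    """Percent of erupted carbon fixed into cell biomass."""
    _check_positive(cell_c_g_per_yr=cell_c_g_per_yr)
    if erupted_c_kg_per_yr <= 0:
        raise ValueError("erupted carbon must be positive")
    return cell_c_g_per_yr / (erupted_c_kg_per_yr * 1000.0) * 100.0


def carbon_budget(inputs: BudgetInputs) -> dict:
    """Full budget report with every intermediate term."""
    n_eruptions = annual_eruptions(inputs.season_days, inputs.eruptions_per_day)
    cell_g = cell_carbon(inputs.cells_per_ml, inputs.fg_c_per_cell,
                         inputs.eruption_volume_m3, n_eruptions)
    erupted_kg = erupted_carbon(inputs.co2_mg_per_l, inputs.hco3_mg_per_l,
                                inputs.eruption_volume_m3, n_eruptions)
    return {
        "inputs": asdict(inputs),
        "eruptions_per_year": n_eruptions,
        "cell_carbon_g_per_yr": cell_g,
        "erupted_carbon_kg_per_yr": erupted_kg,
        "fixed_fraction_percent": fixed_fraction(cell_g, erupted_kg),
    }
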