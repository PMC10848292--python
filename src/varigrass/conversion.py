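"""Reduced-order cellulosic-ethanol conversion model.

Maps a closed whole-biomass composition to process ethanol yield, excess
electricity coproduct, and a biorefinery material-input inventory for a
dilute-acid pretreatment + simultaneous saccharification and fermentation
plant.  The model is linear in the sugar vector:

    ethanol (g/g feed) = sum_i sugar_i * conv_i * 0.511
    process yield (L/Mg) = ethanol (g/g) / 0.789 kg/L * 1000

with overall sugar-to-ethanol conversion fractions taken from corn-stover
operating data (glucose 0.90, arabinose 0.70 - the published endpoints -
and xylose 0.89 by calibration to the cohort-mean process yield; galactose
is not fermented).  0.511 g/g is the fermentation stoichiometry on the
monomeric-sugar basis used throughout; 0.789 kg/L is ethanol density.

Lignin and other unconverted organic solids are burned: the boiler raises
process steam first and the surplus is converted to grid electricity at a
fixed boiler-to-wire efficiency.  Electricity is clamped at zero (a
heat-deficit plant imports, it does not refund).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

from .composition import ClosedComposition

__all__ = [
    "ConversionParams",
    "ConversionResult",
    "process_yield",
    "energy_coproduct",
    "biorefinery_inventory",
    "field_ethanol_yield",
    "convert",
]


@dataclass(frozen=True)
class ConversionParams:
    conv_glucose: float = 0.90
    conv_xylose: float = 0.89
    conv_arabinose: float = 0.70
    conv_galactose: float = 0.0
    stoich_factor: float = 0.511  # g ethanol per g monomeric sugar
    ethanol_density: float = 0.789  # kg/L
    lignin_lhv: float = 21.0  # MJ/kg, applied to all combustible residue
    ethanol_lhv: float = 21.1  # MJ/L
    boiler_electric_efficiency: float = 0.25  # surplus fuel MJ -> electricity MJ
    process_heat_demand: float = 4500.0  # MJ per Mg feed

    def __post_init__(self) -> None:
        for name in ("conv_glucose", "conv_xylose", "conv_arabinose", "conv_galactose"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("stoich_factor", "ethanol_density", "lignin_lhv", "ethanol_lhv"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.boiler_electric_efficiency <= 1.0:
            raise ValueError("boiler_electric_efficiency must be in [0, 1]")
        if self.process_heat_demand < 0:
            raise ValueError("process_heat_demand must be >= 0")


@dataclass(frozen=True)
class ConversionResult:
    process_yield: float  # L ethanol per dry Mg feed
    ethanol_mass_fraction: float  # g ethanol per g feed
    excess_electricity: float = 0.0  # kWh per L ethanol
    biorefinery_inputs: Mapping[str, float] = field(default_factory=dict)  # per L

    def __post_init__(self) -> None:
        if self.process_yield < 0 or self.excess_electricity < 0:
            raise ValueError("yields must be >= 0")


def process_yield(
    closed: ClosedComposition, params: ConversionParams = ConversionParams()
) -> ConversionResult:
    """Process ethanol yield (L per dry Mg) from the closed composition.

    Linear in the sugar vector and independent of lignin, ash and
    extractives.  Bounded above by the stoichiometric ceiling
    FCMF_incl_galactose * 0.511 g/g.
    """
    ethanol_gg = params.stoich_factor * (
        closed.glucan_eq * params.conv_glucose
        + closed.xylan_eq * params.conv_xylose
        + closed.arabinan_eq * params.conv_arabinose
        + closed.galactan_eq * params.conv_galactose
    )
    litres_per_mg = ethanol_gg / params.ethanol_density * 1000.0
    return ConversionResult(
        process_yield=litres_per_mg, ethanol_mass_fraction=ethanol_gg
    )


def combustible_residue(
    closed: ClosedComposition, params: ConversionParams = ConversionParams()
) -> float:
    """Mass fraction of feed burned in the boiler: lignin plus unconverted
    carbohydrates, extractives and protein.  Ash and acetate are excluded
    (mineral / lost to wastewater)."""
    unconverted_sugars = (
        closed.glucan_eq * (1.0 - params.conv_glucose)
        + closed.xylan_eq * (1.0 - params.conv_xylose)
        + closed.arabinan_eq * (1.0 - params.conv_arabinose)
        + closed.galactan_eq * (1.0 - params.conv_galactose)
        + closed.mannan_eq
    )
    return closed.lignin + unconverted_sugars + closed.extractives + closed.protein


def energy_coproduct(
    closed: ClosedComposition,
    result: ConversionResult,
    params: ConversionParams = ConversionParams(),
) -> float:
    """Excess electricity sold to the grid, kWh per L ethanol.

    Fuel energy = combustible residue x lignin LHV; the process heat demand
    is met first and the surplus is converted at the boiler-to-wire
    efficiency.  Clamped at zero when the residue cannot cover the demand
    (a warning is emitted since the plant is then energy-deficient).
    """
    if result.process_yield <= 0:
        return 0.0
    fuel_mj_per_mg = combustible_residue(closed, params) * 1000.0 * params.lignin_lhv
    surplus = fuel_mj_per_mg - params.process_heat_demand
    if surplus < 0:
        warnings.warn(
            "residue fuel does not cover process heat demand; "
            "electricity coproduct clamped to zero",
            stacklevel=2,
        )
        return 0.0
    kwh_per_mg = surplus * params.boiler_electric_efficiency / 3.6
    return kwh_per_mg / result.process_yield


def biorefinery_inventory(
    result: ConversionResult,
    per_mg_inputs: Mapping[str, float],
) -> dict[str, float]:
    """Biorefinery material inputs per litre of ethanol.

    Each input is modelled as a constant consumption per Mg of feed, so the
    per-litre quantity is the constant divided by the process yield -
    higher-FCMF (higher-yield) feedstocks dilute every input.
    """
    if result.process_yield <= 0:
        raise ValueError("process yield must be > 0 to normalize inventory")
    return {name: q / result.process_yield for name, q in per_mg_inputs.items()}


def field_ethanol_yield(process_yield_l_mg: float, commercial_yield_mg_ha: float) -> float:
    """Field ethanol yield (L/ha/yr) = process yield x biomass yield."""
    if process_yield_l_mg < 0 or commercial_yield_mg_ha < 0:
        raise ValueError("yields must be >= 0")
    return process_yield_l_mg * commercial_yield_mg_ha


def convert(
    closed: ClosedComposition,
    params: ConversionParams = ConversionParams(),
    per_mg_inputs: Mapping[str, float] | None = None,
) -> ConversionResult:
    """Full conversion result: yield, electricity coproduct, inventory."""
    base = process_yield(closed, params)
    elec = energy_coproduct(closed, base, params)
    inventory = (
        biorefinery_inventory(base, per_mg_inputs) if per_mg_inputs else {}
    )
    return ConversionResult(
        process_yield=base.process_yield,
        ethanol_mass_fraction=base.ethanol_mass_fraction,
        excess_electricity=elec,
        biorefinery_inputs=inventory,
    )
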