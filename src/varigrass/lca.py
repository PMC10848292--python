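"""Cradle-to-biorefinery-gate attributional LCA per genotype.

Functional unit: 1 L of ethanol.  Impacts: 100-year global warming
potential (GWP, g CO2e/L), cumulative energy demand (CED, MJ/L) and the
AWARE water-scarcity indicator (m^3 world-eq/L).

Scope follows the feedstock study conventions: all agricultural and
logistics operations of a 10-year switchgrass rotation with 9 harvested
years (establishment inputs amortized over the harvested years); both
herbicides applied in a single sprayer pass; grass seed trucked 161 km;
rain-fed cultivation (no irrigation water in the agriculture inventory);
ethanol combustion, biogenic CO2, soil carbon and land-use change all out
of scope.  Excess electricity sold to the grid is a coproduct and impacts
are attributed to ethanol by energy-based allocation
(ethanol LHV / (ethanol LHV + electricity)).

The characterization-factor table ships as a packaged fixture
(``data/inventory_factors.csv``).  It is a synthetic, calibrated stand-in
for a licensed background inventory database (which cannot be
redistributed): input quantities are agronomically representative, and a
small number of factors were calibrated once against published cohort
impact anchors, then frozen.  Absolute impact values are therefore
comparative between genotypes, not database-grade absolutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "ImpactFactorTable",
    "RotationParams",
    "LifeCycleInventory",
    "ImpactResult",
    "load_default_table",
    "assemble_inventory",
    "allocation_fraction",
    "characterize",
]

STAGES = ("agriculture", "logistics", "biorefinery")
IMPACTS = ("gwp", "ced", "aware")


@dataclass(frozen=True)
class RotationParams:
    """Rotation accounting: 10-year stand with 9 harvested years."""

    rotation_years: int = 10
    harvested_years: int = 9

    def __post_init__(self) -> None:
        if not 1 <= self.harvested_years <= self.rotation_years:
            raise ValueError("harvested_years must be in [1, rotation_years]")


class ImpactFactorTable:
    """Per-input characterization factors plus foreground quantities.

    Wraps the fixture DataFrame; rows carry the input name, life-cycle
    stage, unit, foreground quantity with its basis (per_ha_yr,
    per_ha_rotation, per_Mg, per_Mg_feed) and the three characterization
    factors (GWP kg CO2e/unit, CED MJ/unit, AWARE m^3/unit).
    """

    def __init__(self, frame: pd.DataFrame):
        required = {
            "input_name",
            "stage",
            "unit",
            "quantity",
            "quantity_basis",
            "gwp_kg_co2e_per_unit",
            "ced_mj_per_unit",
            "aware_m3_per_unit",
        }
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"factor table missing columns: {sorted(missing)}")
        if frame["input_name"].duplicated().any():
            raise ValueError("duplicate input names in factor table")
        neg = frame[
            (frame[["gwp_kg_co2e_per_unit", "ced_mj_per_unit", "aware_m3_per_unit"]] < 0).any(axis=1)
        ]
        if len(neg):
            raise ValueError(f"negative factors for {list(neg.input_name)}")
        bad_stage = set(frame["stage"]) - set(STAGES)
        if bad_stage:
            raise ValueError(f"unknown stages: {sorted(bad_stage)}")
        self.frame = frame.set_index("input_name", drop=False)

    def factors(self, name: str) -> tuple[float, float, float]:
        try:
            row = self.frame.loc[name]
        except KeyError:
            raise KeyError(f"no characterization factors for input {name!r}") from None
        return (
            float(row.gwp_kg_co2e_per_unit),
            float(row.ced_mj_per_unit),
            float(row.aware_m3_per_unit),
        )

    def stage_rows(self, stage: str) -> pd.DataFrame:
        return self.frame[self.frame["stage"] == stage]

    def biorefinery_per_mg(self) -> dict[str, float]:
        """Biorefinery input constants (quantity per Mg feed)."""
        rows = self.stage_rows("biorefinery")
        return dict(zip(rows.input_name, rows.quantity.astype(float)))


def load_default_table() -> ImpactFactorTable:
    """Load the packaged synthetic/calibrated factor fixture."""
    with resources.files("varigrass.data").joinpath("inventory_factors.csv").open() as fh:
        return ImpactFactorTable(pd.read_csv(fh))


def load_table(path: str | Path) -> ImpactFactorTable:
    return ImpactFactorTable(pd.read_csv(path))


@dataclass(frozen=True)
class LifeCycleInventory:
    """Per-litre inventory for one genotype, by stage."""

    agriculture: Mapping[str, float]
    logistics: Mapping[str, float]
    biorefinery: Mapping[str, float]
    coproduct_electricity: float  # kWh per L

    def __post_init__(self) -> None:
        for stage in (self.agriculture, self.logistics, self.biorefinery):
            for name, q in stage.items():
                if q < 0:
                    raise ValueError(f"negative inventory quantity for {name!r}")
        if self.coproduct_electricity < 0:
            raise ValueError("coproduct electricity must be >= 0")


@dataclass(frozen=True)
class ImpactResult:
    gwp: float  # g CO2e / L
    ced: float  # MJ / L
    aware: float  # m^3 / L
    contributions: Mapping[str, Mapping[str, float]] = field(default_factory=dict)


def assemble_inventory(
    commercial_yield: float,
    process_yield: float,
    excess_electricity: float,
    table: ImpactFactorTable | None = None,
    rotation: RotationParams = RotationParams(),
) -> LifeCycleInventory:
    """Per-litre inventory from the genotype's yields.

    Agriculture scales with land demand: quantity per ha-year (rotation
    entries amortized over the harvested years) divided by the field
    ethanol yield (L/ha/yr).  Logistics and biorefinery inputs are per-Mg
    constants divided by the process yield.  Deterministic.
    """
    table = table or load_default_table()
    if commercial_yield <= 0 or process_yield <= 0:
        raise ValueError("yields must be > 0 to normalize per litre")
    field_l_per_ha = commercial_yield * process_yield
    agriculture: dict[str, float] = {}
    for row in table.stage_rows("agriculture").itertuples():
        q = float(row.quantity)
        if row.quantity_basis == "per_ha_rotation":
            q /= rotation.harvested_years
        elif row.quantity_basis != "per_ha_yr":
            raise ValueError(
                f"unsupported agriculture basis {row.quantity_basis!r}"
            )
        agriculture[row.input_name] = q / field_l_per_ha
    logistics = {
        row.input_name: float(row.quantity) / process_yield
        for row in table.stage_rows("logistics").itertuples()
    }
    biorefinery = {
        row.input_name: float(row.quantity) / process_yield
        for row in table.stage_rows("biorefinery").itertuples()
    }
    return LifeCycleInventory(
        agriculture=agriculture,
        logistics=logistics,
        biorefinery=biorefinery,
        coproduct_electricity=excess_electricity,
    )


def allocation_fraction(ethanol_lhv: float, electricity_kwh_per_l: float) -> float:
    """Energy-based allocation of impacts to ethanol, in (0, 1].

    fraction = LHV / (LHV + 3.6 * electricity), with the ethanol lower
    heating value in MJ/L and electricity in kWh/L (3.6 MJ/kWh).
    """
    if ethanol_lhv <= 0:
        raise ValueError("ethanol LHV must be > 0")
    if electricity_kwh_per_l < 0:
        raise ValueError("electricity must be >= 0")
    return ethanol_lhv / (ethanol_lhv + 3.6 * electricity_kwh_per_l)


def characterize(
    inventory: LifeCycleInventory,
    table: ImpactFactorTable | None = None,
    allocation: float = 1.0,
) -> ImpactResult:
    """Characterize the inventory into GWP/CED/AWARE per litre.

    Each impact is allocation x sum(quantity x factor); GWP is reported in
    grams.  Per-stage contributions sum exactly to the totals.  Raises
    KeyError listing any inventory name missing from the factor table.
    """
    table = table or load_default_table()
    if not 0.0 < allocation <= 1.0:
        raise ValueError("allocation must be in (0, 1]")
    stages = {
        "agriculture": inventory.agriculture,
        "logistics": inventory.logistics,
        "biorefinery": inventory.biorefinery,
    }
    missing = [
        name
        for quantities in stages.values()
        for name in quantities
        if name not in table.frame.index
    ]
    if missing:
        raise KeyError(f"no characterization factors for: {sorted(set(missing))}")
    contributions: dict[str, dict[str, float]] = {imp: {} for imp in IMPACTS}
    for stage_name, quantities in stages.items():
        g = e = w = 0.0
        for name, q in quantities.items():
            fg, fe, fw = table.factors(name)
            g += q * fg
            e += q * fe
            w += q * fw
        contributions["gwp"][stage_name] = allocation * g * 1000.0  # kg -> g
        contributions["ced"][stage_name] = allocation * e
        contributions["aware"][stage_name] = allocation * w
    return ImpactResult(
        gwp=sum(contributions["gwp"].values()),
        ced=sum(contributions["ced"].values()),
        aware=sum(contributions["aware"].values()),
        contributions=contributions,
    )
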