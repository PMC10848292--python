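"""Cell-wall composition closure.

Analytical composition of herbaceous biomass is reported on a destarched,
ethanol-extracted basis (the basis on which hydrolysate sugar assays and
pyrolysis lignin estimates are made).  Down-stream process models need
component mass fractions of *whole dry biomass* that close to 100%.  This
module converts between the two bases and completes the mass balance:

1. ``to_whole_biomass`` rescales the measured sugar and lignin fractions by
   the extraction factor (default 0.95) that accounts for the mass removed
   by destarching and ethanol extraction.
2. ``close_mass_balance`` adds the assumed minor components (mannan,
   acetate, sucrose, protein) and assigns the remainder of the mass to
   non-ethanol-soluble extractives so the component vector sums to one.
3. ``fcmf`` computes the fermentable carbohydrate mass fraction
   (glucan + xylan + arabinan; galactan is excluded because it is not
   fermented in the reference conversion model).

Carbohydrates are carried on a monomeric-equivalent basis throughout (no
anhydro correction); the reference conversion model's stoichiometry is
expressed on the same basis, so the two cancel consistently.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

__all__ = [
    "RawComposition",
    "ClosedComposition",
    "ClosureDefaults",
    "CompositionError",
    "EXTRACTION_FACTOR",
    "to_whole_biomass",
    "close_mass_balance",
    "fcmf",
]

#: Mass fraction of whole dry biomass remaining after destarching and
#: ethanol extraction; measured fractions are multiplied by this factor to
#: re-express them on the whole-biomass basis.
EXTRACTION_FACTOR = 0.95


class CompositionError(ValueError):
    """Raised when a composition is infeasible (components exceed unity)."""


@dataclass(frozen=True)
class RawComposition:
    """Measured composition of one genotype.

    Sugar fields are monomeric-equivalent mass fractions; ``lignin`` and
    ``ash`` are mass fractions; ``sg_ratio`` is the dimensionless
    syringyl/guaiacyl lignin monomer ratio (stored but not used by the
    conversion model).  Whether the fractions are on the extracted or the
    whole-biomass basis is a property of the pipeline stage, not the type;
    ``to_whole_biomass`` must be applied exactly once before closure.
    """

    glucose: float
    xylose: float
    galactose: float
    arabinose: float
    lignin: float
    sg_ratio: float
    ash: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "sg_ratio":
                if not v > 0:
                    raise CompositionError(f"sg_ratio must be > 0, got {v!r}")
            elif not 0.0 <= v <= 1.0:
                raise CompositionError(f"{f.name} must be in [0, 1], got {v!r}")


@dataclass(frozen=True)
class ClosureDefaults:
    """Assumed minor-component mass fractions of whole dry biomass.

    Defaults follow the reference process model for compositions where the
    minor components were not measured: mannan 0, acetate 2.00 wt%,
    sucrose 0, protein 3.10 wt%.
    """

    mannan_eq: float = 0.0
    acetate: float = 0.020
    sucrose: float = 0.0
    protein: float = 0.031


@dataclass(frozen=True)
class ClosedComposition:
    """Whole-biomass component mass fractions summing to one."""

    glucan_eq: float
    xylan_eq: float
    galactan_eq: float
    arabinan_eq: float
    mannan_eq: float
    lignin: float
    ash: float
    acetate: float
    sucrose: float
    protein: float
    extractives: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @property
    def total(self) -> float:
        return sum(self.as_dict().values())


def to_whole_biomass(
    raw: RawComposition,
    factor: float = EXTRACTION_FACTOR,
    rescale_ash: bool = False,
) -> RawComposition:
    """Re-express measured sugar and lignin fractions on the whole-biomass basis.

    Multiplies the four sugars and lignin by ``factor``.  ``sg_ratio`` is a
    ratio and is unchanged.  Ash is measured on whole biomass and left
    unchanged by default; pass ``rescale_ash=True`` if the ash assay shared
    the extracted basis.

    The operation is linear and intentionally not idempotent: apply it
    exactly once in a pipeline.
    """
    if not 0.0 < factor <= 1.0:
        raise CompositionError(f"extraction factor must be in (0, 1], got {factor!r}")
    return RawComposition(
        glucose=raw.glucose * factor,
        xylose=raw.xylose * factor,
        galactose=raw.galactose * factor,
        arabinose=raw.arabinose * factor,
        lignin=raw.lignin * factor,
        sg_ratio=raw.sg_ratio,
        ash=raw.ash * factor if rescale_ash else raw.ash,
    )


def close_mass_balance(
    raw_whole: RawComposition,
    defaults: ClosureDefaults = ClosureDefaults(),
) -> ClosedComposition:
    """Complete the whole-biomass mass balance.

    Carbohydrate fields are taken from the monomer-equivalent inputs, the
    minor components from ``defaults``, and non-ethanol-soluble extractives
    absorb the remainder so the fields sum to exactly one.

    Raises :class:`CompositionError` if the named components already exceed
    unity (negative extractives), reporting the overfull components.
    """
    named = {
        "glucan_eq": raw_whole.glucose,
        "xylan_eq": raw_whole.xylose,
        "galactan_eq": raw_whole.galactose,
        "arabinan_eq": raw_whole.arabinose,
        "mannan_eq": defaults.mannan_eq,
        "lignin": raw_whole.lignin,
        "ash": raw_whole.ash,
        "acetate": defaults.acetate,
        "sucrose": defaults.sucrose,
        "protein": defaults.protein,
    }
    subtotal = sum(named.values())
    extractives = 1.0 - subtotal
    if extractives < 0.0:
        top = sorted(named.items(), key=lambda kv: kv[1], reverse=True)[:3]
        listing = ", ".join(f"{k}={v:.4f}" for k, v in top)
        raise CompositionError(
            f"components sum to {subtotal:.4f} > 1; largest: {listing}"
        )
    return ClosedComposition(extractives=extractives, **named)


def fcmf(closed: ClosedComposition) -> float:
    """Fermentable carbohydrate mass fraction: glucan + xylan + arabinan.

    Galactan is excluded (not fermented in the reference conversion model).
    Monotone nondecreasing in each included component.
    """
    return closed.glucan_eq + closed.xylan_eq + closed.arabinan_eq
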