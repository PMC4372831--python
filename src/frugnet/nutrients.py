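"""Fruit proximate composition and the derived sugar estimate.

Laboratory assays report relative humidity (RH), proteins, lipids and fibre as
percentages of fruit mass.  The nitrogen-free extractive substances (NFES) are
the residual fraction

    NFES = 100 - RH - proteins - lipids - fibre

and the sugar content is estimated from the remaining organic material as

    sugars = NFES * 100 / (100 - RH).

All quantities are percentages in [0, 100].
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class FruitNutrients:
    """Proximate composition of a fruit species (percent).

    ``nfes`` and ``sugars`` are derived quantities; use
    :func:`sugars_from_composition` to fill them in from the four assayed
    fractions.
    """

    relative_humidity: float
    proteins: float
    lipids: float
    fibre: float
    nfes: float = float("nan")
    sugars: float = float("nan")

    def __post_init__(self) -> None:
        for field in ("relative_humidity", "proteins", "lipids", "fibre"):
            value = getattr(self, field)
            if not 0.0 <= value <= 100.0:
                raise ValueError(f"{field}={value} outside [0, 100]")


def sugars_from_composition(n: FruitNutrients) -> FruitNutrients:
    """Complete a composition record with its NFES and sugar percentages.

    Raises ``ValueError`` if RH >= 100 (sugar estimate undefined) or if the
    assayed fractions exceed 100 % (negative NFES).
    """
    rh = n.relative_humidity
    if rh >= 100.0:
        raise ValueError(f"relative humidity {rh} must be < 100 to estimate sugars")
    nfes = 100.0 - rh - n.proteins - n.lipids - n.fibre
    if nfes < 0.0:
        raise ValueError(
            f"composition exceeds total mass: NFES = {nfes:.4f} < 0 "
            f"(RH {rh} + proteins {n.proteins} + lipids {n.lipids} + fibre {n.fibre})"
        )
    sugars = nfes * 100.0 / (100.0 - rh)
    return FruitNutrients(rh, n.proteins, n.lipids, n.fibre, nfes=nfes, sugars=sugars)


def to_dry_mass_basis(value_fresh: float, relative_humidity: float) -> float:
    """Convert a percent-of-fresh-mass fraction to percent of dry mass.

    ``value_dry = value_fresh * 100 / (100 - RH)``.  Assay reports mix the
    two bases; the NFES/sugar arithmetic above is applied to the reported
    percentages as printed, and this converter is provided for callers whose
    laboratory reports protein/lipid/fibre on the other basis.  Note the
    sugar estimate (sugars = NFES * 100 / (100 - RH)) is exactly the NFES
    residue re-expressed on a dry-mass basis.
    """
    if not 0.0 <= relative_humidity < 100.0:
        raise ValueError("relative humidity must be in [0, 100)")
    return value_fresh * 100.0 / (100.0 - relative_humidity)
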