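"""Closed-form bark allometry: relative bark thickness/area and bark-carbon conversion.

All fractions (RBT, RBA, BFI, carbon fraction) are proportions in [0, 1] internally;
percent is a presentation concern (see :mod:`barkcarbon.formatting`). Units are fixed:
diameters and thicknesses in cm, heights in m, basal area in m^2, volume in m^3,
biomass in kg, density in kg/m^3, carbon in kgC. No unit inference is performed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

from .errors import BarkDomainError, ConfigurationError

__all__ = [
    "StemGeometry",
    "CarbonInputs",
    "DensityPair",
    "relative_bark_thickness",
    "relative_bark_area",
    "bark_carbon",
    "density_deficit",
    "geometry_from_model",
]

CARBON_MODES = ("basal_area", "volume", "biomass", "tree_carbon")


@dataclass(frozen=True)
class StemGeometry:
    """One stem cross-section: diameter over bark and maximum bark thickness, both cm.

    ``bt_max`` is the ridge-to-wood thickness — the thickness a diameter tape or
    calliper implicitly assumes all around the stem. The diameter under bark is
    ``dub = dob - 2 * bt_max`` and must stay positive.
    """

    dob: float
    bt_max: float

    def __post_init__(self) -> None:
        if not self.dob > 0:
            raise BarkDomainError(f"dob must be positive, got {self.dob}")
        if self.bt_max < 0:
            raise BarkDomainError(f"bt_max must be non-negative, got {self.bt_max}")
        if self.bt_max >= self.dob / 2:
            raise BarkDomainError(
                f"bt_max={self.bt_max} must be < dob/2={self.dob / 2} "
                "(diameter under bark would be non-positive)"
            )

    @property
    def dub(self) -> float:
        """Diameter under bark, cm."""
        return self.dob - 2.0 * self.bt_max


def geometry_from_model(dob: float, model: Callable[[float], float]) -> StemGeometry:
    """Build a :class:`StemGeometry` from a user-supplied bark-thickness model.

    ``model`` maps diameter over bark (cm) to maximum bark thickness (cm). Any
    published allometric bark-thickness function can be plugged in here; none is
    bundled because coefficients are species- and region-specific.
    """
    return StemGeometry(dob=dob, bt_max=float(model(dob)))


def relative_bark_thickness(geom: StemGeometry) -> float:
    """Relative bark thickness RBT = 2*BT_max / (DoB - 2*BT_max), a proportion.

    Bark thickness is expressed relative to the *under-bark* (wood) diameter to
    avoid autocorrelation with the over-bark measurement. Strictly increasing in
    ``bt_max`` at fixed ``dob``; zero iff there is no bark.
    """
    return 2.0 * geom.bt_max / (geom.dob - 2.0 * geom.bt_max)


def relative_bark_area(geom: StemGeometry) -> float:
    """Relative bark area RBA = (4*BT_max*DoB - 4*BT_max^2) / DoB^2, a proportion.

    This is the idealized bark annulus as a fraction of the over-bark stem
    cross-section, assuming a circular stem; algebraically identical to
    ``1 - (dub/dob)**2``. Lies in [0, 1).
    """
    return (4.0 * geom.bt_max * geom.dob - 4.0 * geom.bt_max**2) / geom.dob**2


@dataclass(frozen=True)
class CarbonInputs:
    """Stand/tree quantities feeding the bark-carbon conversions.

    At least one of ``basal_area+height+form_factor``, ``volume``, ``biomass`` or
    ``tree_carbon`` must be present. ``bark_density`` (kg/m^3, displacement method)
    and ``carbon_fraction`` (kgC/kg, dry combustion) are always required even
    though the biomass and tree-carbon modes do not use both.
    """

    bark_density: float
    carbon_fraction: float
    basal_area: Optional[float] = None
    height: Optional[float] = None
    form_factor: Optional[float] = None
    volume: Optional[float] = None
    biomass: Optional[float] = None
    tree_carbon: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.bark_density > 0:
            raise BarkDomainError(f"bark_density must be positive, got {self.bark_density}")
        if not 0 < self.carbon_fraction <= 1:
            raise BarkDomainError(
                f"carbon_fraction must be in (0, 1], got {self.carbon_fraction}"
            )
        for name in ("basal_area", "height", "form_factor", "volume", "biomass", "tree_carbon"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise BarkDomainError(f"{name} must be positive when provided, got {v}")
        has_ba = all(
            getattr(self, n) is not None for n in ("basal_area", "height", "form_factor")
        )
        if not (has_ba or self.volume is not None or self.biomass is not None
                or self.tree_carbon is not None):
            raise ConfigurationError(
                "need one of basal_area+height+form_factor, volume, biomass or tree_carbon"
            )


def bark_carbon(inputs: CarbonInputs, rba: float, bfi: float, mode: str) -> float:
    """Bark carbon (kgC) for one tree or stand aggregate.

    mode='basal_area'  -> BA * H * FF * RBA * bark_density * carbon_fraction * BFI
    mode='volume'      -> V * RBA * bark_density * carbon_fraction * BFI
    mode='biomass'     -> BM * RBA * carbon_fraction * BFI
    mode='tree_carbon' -> TreeC * RBA * BFI

    The biomass and tree-carbon modes inherit wood density (and carbon fraction)
    from the parent quantity, i.e. they assume bark density equals wood density
    and therefore overestimate bark carbon for most hardwoods; multiplying by the
    bark fissure index BFI removes the air-filled fissure space in every mode.
    """
    if not 0 <= rba < 1:
        raise BarkDomainError(f"rba must be in [0, 1), got {rba}")
    if not 0 < bfi <= 1:
        raise BarkDomainError(f"bfi must be in (0, 1], got {bfi}")
    if mode == "basal_area":
        for name in ("basal_area", "height", "form_factor"):
            if getattr(inputs, name) is None:
                raise ConfigurationError(f"mode 'basal_area' requires {name}")
        v = inputs.basal_area * inputs.height * inputs.form_factor
        return v * rba * inputs.bark_density * inputs.carbon_fraction * bfi
    if mode == "volume":
        if inputs.volume is None:
            raise ConfigurationError("mode 'volume' requires volume")
        return inputs.volume * rba * inputs.bark_density * inputs.carbon_fraction * bfi
    if mode == "biomass":
        if inputs.biomass is None:
            raise ConfigurationError("mode 'biomass' requires biomass")
        return inputs.biomass * rba * inputs.carbon_fraction * bfi
    if mode == "tree_carbon":
        if inputs.tree_carbon is None:
            raise ConfigurationError("mode 'tree_carbon' requires tree_carbon")
        return inputs.tree_carbon * rba * bfi
    raise ConfigurationError(f"unknown mode {mode!r}; expected one of {CARBON_MODES}")


@dataclass(frozen=True)
class DensityPair:
    """Basic densities of bark and wood for one species, kg/m^3."""

    bark_density: float
    wood_density: float

    def __post_init__(self) -> None:
        if not self.bark_density > 0:
            raise BarkDomainError(f"bark_density must be positive, got {self.bark_density}")
        if not self.wood_density > 0:
            raise BarkDomainError(f"wood_density must be positive, got {self.wood_density}")


def density_deficit(pair: DensityPair) -> float:
    """How much less dense bark is than wood, in percent of wood density.

    Negative when bark is denser than wood. Quantifies the error made by the
    common assumption that bark density equals wood density.
    """
    return 100.0 * (pair.wood_density - pair.bark_density) / pair.wood_density
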