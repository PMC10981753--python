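"""Materials, layer stacks and pillar-lattice geometry.

All quantities are SI internally (metres, kg/m^3, m/s, Pa·s/m).  Acoustic
impedances are reported in MRayl (1 MRayl = 1e6 Pa·s/m) only at the API
boundary, mirroring how transducer datasheets quote them.

The piezoelectric layer of a pillar transducer is an effective medium: an
array of hexagonal polymer pillars with air-filled kerfs, sandwiched between
two continuous polymer films.  Its effective acoustic impedance and wave
speed are what a through-thickness transmission measurement sees, and the
frequency-dependent permittivity/loss laws are fitted from electrical
impedance spectra.  :class:`PiezoMaterial` carries those fitted laws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

EPS0 = 8.8541878128e-12  # vacuum permittivity, F/m


class InvalidMaterialError(ValueError):
    """Raised when a material parameter is outside its physical domain."""


@dataclass(frozen=True)
class Material:
    """Homogeneous acoustic medium.

    Parameters
    ----------
    name : str
    density : float
        kg/m^3, > 0.
    wave_speed : float
        Compressional wave speed, m/s, > 0.
    mech_loss_tangent : float
        Mechanical loss tangent tan(delta_m) >= 0.  Enters the wave speed as
        a complex stiffness, ``c -> c * (1 + j tan(delta_m)/2)``.
    """

    name: str
    density: float
    wave_speed: float
    mech_loss_tangent: float = 0.0

    def __post_init__(self) -> None:
        if self.density <= 0 or self.wave_speed <= 0:
            raise InvalidMaterialError(
                f"{self.name}: density and wave_speed must be positive "
                f"(got {self.density}, {self.wave_speed})"
            )
        if self.mech_loss_tangent < 0:
            raise InvalidMaterialError(
                f"{self.name}: mech_loss_tangent must be >= 0"
            )

    @property
    def impedance(self) -> float:
        """Characteristic acoustic impedance, Pa·s/m (Rayl)."""
        return self.density * self.wave_speed

    @property
    def complex_wave_speed(self) -> complex:
        """Wave speed with mechanical loss folded in as complex stiffness."""
        return self.wave_speed * (1.0 + 0.5j * self.mech_loss_tangent)


@dataclass(frozen=True)
class PiezoMaterial(Material):
    """Piezoelectric effective medium with fitted frequency-dependent laws.

    The relative clamped permittivity and dielectric loss tangent follow the
    linear-in-frequency laws (frequency in MHz)::

        K33(f)      = a - b * f_MHz
        tan_de(f)   = c0 + c1 * f_MHz

    Defaults are the fitted values for the embossed P(VDF-TrFE) pillar
    composite: k_t = 0.185, K = 6.5 - 0.0088 f, tan_de = 0.075 + 0.04 f,
    tan_dm = 0.125.  ``d33`` is informational only.
    """

    k_t: float = 0.185
    permittivity_law: tuple[float, float] = (6.5, 0.0088)
    dielectric_loss_law: tuple[float, float] = (0.075, 0.04)
    d33: float | None = None  # pC/N, not used by the 1-D model

    def __post_init__(self) -> None:
        super().__post_init__()
        if not 0.0 < self.k_t < 1.0:
            raise InvalidMaterialError(f"k_t must be in (0, 1), got {self.k_t}")

    def rel_permittivity(self, f_hz: np.ndarray | float) -> np.ndarray | float:
        """Relative clamped permittivity K33(f); raises if non-positive."""
        a, b = self.permittivity_law
        k = a - b * np.asarray(f_hz) / 1e6
        if np.any(k <= 0):
            raise InvalidMaterialError(
                "relative permittivity law is non-positive at the requested "
                "frequency: outside the declared band"
            )
        return k

    def dielectric_loss(self, f_hz: np.ndarray | float) -> np.ndarray | float:
        """Dielectric loss tangent tan(delta_e)(f)."""
        c0, c1 = self.dielectric_loss_law
        t = c0 + c1 * np.asarray(f_hz) / 1e6
        if np.any(t < 0):
            raise InvalidMaterialError("dielectric loss tangent is negative")
        return t

    def complex_permittivity(self, f_hz: np.ndarray | float) -> np.ndarray | complex:
        """Absolute clamped permittivity eps33^S (1 - j tan_de), F/m."""
        return (
            self.rel_permittivity(f_hz)
            * EPS0
            * (1.0 - 1j * self.dielectric_loss(f_hz))
        )


@dataclass(frozen=True)
class Layer:
    """A finite-thickness layer of a material."""

    material: Material
    thickness: float  # m

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise InvalidMaterialError(
                f"layer thickness must be > 0, got {self.thickness}"
            )


@dataclass(frozen=True)
class TransducerStack:
    """Ordered layer stack of a thickness-mode transducer.

    ``layers`` run from the backing side to the load side and must contain
    exactly one :class:`PiezoMaterial` layer.  ``backing_medium`` and
    ``load_medium`` are semi-infinite.
    """

    layers: tuple[Layer, ...]
    element_area: float  # m^2
    backing_medium: Material
    load_medium: Material

    def __post_init__(self) -> None:
        if self.element_area <= 0:
            raise InvalidMaterialError("element_area must be > 0")
        piezo = [
            i for i, lay in enumerate(self.layers)
            if isinstance(lay.material, PiezoMaterial)
        ]
        if len(piezo) != 1:
            raise InvalidMaterialError(
                f"stack must contain exactly one piezo layer, found {len(piezo)}"
            )
        object.__setattr__(self, "_piezo_index", piezo[0])

    @property
    def piezo_index(self) -> int:
        return self._piezo_index  # type: ignore[attr-defined]

    @property
    def piezo_layer(self) -> Layer:
        return self.layers[self.piezo_index]

    @property
    def back_layers(self) -> tuple[Layer, ...]:
        """Passive layers between the piezo and the backing medium,
        ordered from the piezo outwards."""
        return tuple(reversed(self.layers[: self.piezo_index]))

    @property
    def front_layers(self) -> tuple[Layer, ...]:
        """Passive layers between the piezo and the load medium,
        ordered from the piezo outwards."""
        return self.layers[self.piezo_index + 1:]

    def with_load(self, load: Material) -> "TransducerStack":
        return TransducerStack(
            self.layers, self.element_area, self.backing_medium, load
        )


@dataclass(frozen=True)
class PillarLattice:
    """Hexagonal pillar lattice: across-flats pillar diameter plus kerf.

    The pillars are similar hexagons on a hexagonal lattice, so the fill
    factor is ``(diameter / pitch)**2`` and the unit-cell area is
    ``sqrt(3)/2 * pitch**2``.
    """

    pillar_diameter: float  # m, across flats
    kerf: float  # m

    def __post_init__(self) -> None:
        if self.pillar_diameter <= 0:
            raise InvalidMaterialError("pillar_diameter must be > 0")
        if self.kerf < 0:
            raise InvalidMaterialError("kerf must be >= 0")

    @property
    def pitch(self) -> float:
        return self.pillar_diameter + self.kerf

    @property
    def unit_cell_area(self) -> float:
        return math.sqrt(3.0) / 2.0 * self.pitch**2


@dataclass(frozen=True)
class RectangularElement:
    width: float  # m
    height: float  # m

    @property
    def area(self) -> float:
        if self.width <= 0 or self.height <= 0:
            raise InvalidMaterialError("element dimensions must be > 0")
        return self.width * self.height


@dataclass(frozen=True)
class CircularElement:
    radius: float  # m

    @property
    def area(self) -> float:
        if self.radius <= 0:
            raise InvalidMaterialError("element radius must be > 0")
        return math.pi * self.radius**2


# ---------------------------------------------------------------------------
# interface acoustics


def acoustic_impedance(material: Material) -> float:
    """Acoustic impedance of a material in MRayl (density * wave speed)."""
    return material.impedance / 1e6


def transmission_coefficient(z_source: float, z_load: float) -> float:
    """Pressure-amplitude transmission at a planar normal-incidence interface.

    ``T = 2 * z_load / (z_source + z_load)``; both impedances in the same
    units (conventionally MRayl).  This is the pressure (not intensity)
    coefficient: a matched interface gives exactly 1.
    """
    if z_source <= 0 or z_load <= 0:
        raise InvalidMaterialError("impedances must be positive")
    return 2.0 * z_load / (z_source + z_load)


def fill_factor(lattice: PillarLattice) -> float:
    """Active-area fraction of similar hexagonal pillars on a hexagonal
    lattice: ``(diameter / pitch)**2``."""
    return (lattice.pillar_diameter / lattice.pitch) ** 2


def pillar_count(
    lattice: PillarLattice,
    element: RectangularElement | CircularElement,
) -> int:
    """Number of pillars under an electrode, continuum approximation.

    Element area divided by the hexagonal unit-cell area, rounded to the
    nearest integer.  Valid when the element is much larger than one cell;
    no boundary-pillar correction is applied.
    """
    cell = lattice.unit_cell_area
    area = element.area
    if area < cell:
        raise InvalidMaterialError(
            "element is smaller than one lattice unit cell"
        )
    return round(area / cell)


# ---------------------------------------------------------------------------
# reference materials

WATER = Material("water", density=1000.0, wave_speed=1500.0)
AIR = Material("air", density=1.2, wave_speed=343.0)
#: Paraffin-type coupling oil; acoustically interchangeable with water here.
OIL = Material("oil", density=920.0, wave_speed=1630.0)
#: Handbook constants for spin-on polyimide foil.
POLYIMIDE = Material("polyimide", density=1420.0, wave_speed=2200.0)


def pvdf_trfe(
    wave_speed: float = 2100.0,
    impedance_mrayl: float = 3.7,
    k_t: float = 0.185,
    permittivity_law: tuple[float, float] = (6.5, 0.0088),
    dielectric_loss_law: tuple[float, float] = (0.075, 0.04),
    mech_loss_tangent: float = 0.125,
) -> PiezoMaterial:
    """Effective-medium P(VDF-TrFE) pillar composite.

    The density is not measured directly on the composite; it is set from
    the measured impedance and wave speed as ``rho = Z / c`` (default
    3.7 MRayl / 2100 m/s ≈ 1762 kg/m^3).
    """
    return PiezoMaterial(
        name="P(VDF-TrFE) pillar composite",
        density=impedance_mrayl * 1e6 / wave_speed,
        wave_speed=wave_speed,
        mech_loss_tangent=mech_loss_tangent,
        k_t=k_t,
        permittivity_law=permittivity_law,
        dielectric_loss_law=dielectric_loss_law,
    )
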