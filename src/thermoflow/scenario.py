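"""Scenario definitions: geometry, materials, boundary conditions, flow.

Coordinate convention (right-handed, all lengths in mm):
  * x — flow direction along the vessel axis,
  * y — across the vessel, on the skin plane,
  * z — vertical, positive up, origin at the actuator center on the top
    (skin) surface of the phantom.

The phantom block occupies z in [-Lz, 0]; the interlayer air gap and the
actuator occupy z > 0.  Vessel depth ``d`` is the distance from the top
surface to the *top* of the cylindrical channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = [
    "MaterialProperties",
    "PhantomGeometry",
    "ActuatorSpec",
    "SensorLayout",
    "AmbientConditions",
    "FlowCondition",
    "Scenario",
    "default_materials",
    "default_scenario",
]


@dataclass(frozen=True)
class MaterialProperties:
    """Bulk thermal properties of one material region.

    Parameters
    ----------
    label
        Human-readable name ("pdms", "water", ...).
    thermal_conductivity
        k in W/(m K).
    specific_heat
        c_p in J/(kg K).
    density
        rho in kg/m^3.
    """

    label: str
    thermal_conductivity: float
    specific_heat: float
    density: float

    def __post_init__(self) -> None:
        for name in ("thermal_conductivity", "specific_heat", "density"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{self.label}: {name} must be strictly positive")

    @property
    def volumetric_heat_capacity(self) -> float:
        """rho * c_p in J/(m^3 K)."""
        return self.density * self.specific_heat


def default_materials() -> dict[str, MaterialProperties]:
    """Material table for the benchtop phantom model.

    PDMS, water and copper use the benchtop study's stated conductivities
    and heat capacities; densities use handbook values.  The interlayer gap
    is modeled as still air (pure conduction, no convection cells within the
    1.5 mm gap).  "silicone" is the optional tubing-wall material.
    """
    return {
        "pdms": MaterialProperties("pdms", 0.16, 1460.0, 965.0),
        "water": MaterialProperties("water", 0.6, 4184.0, 1000.0),
        "copper": MaterialProperties("copper", 400.0, 385.0, 8960.0),
        "air": MaterialProperties("air", 0.026, 1005.0, 1.2),
        "silicone": MaterialProperties("silicone", 0.2, 1300.0, 1100.0),
    }


@dataclass(frozen=True)
class PhantomGeometry:
    """Skin-phantom block with an embedded cylindrical channel.

    ``block_mm`` is (x extent, y extent, z thickness).  The channel axis runs
    along x, centered in y.  ``vessel_depth`` is measured from the top
    surface to the top of the channel (outer wall if ``wall_thickness`` > 0).
    """

    block_mm: tuple[float, float, float] = (30.0, 20.0, 10.0)
    channel_diameter: float = 2.5
    vessel_depth: float = 1.0
    wall_thickness: float = 0.0
    wall_material: Optional[str] = None

    def __post_init__(self) -> None:
        if self.channel_diameter <= 0:
            raise ValueError("channel_diameter must be positive")
        if self.vessel_depth <= 0:
            raise ValueError("vessel_depth must be positive")
        if self.wall_thickness < 0:
            raise ValueError("wall_thickness must be nonnegative")
        total = self.vessel_depth + self.channel_diameter + 2 * self.wall_thickness
        if total > self.block_mm[2]:
            raise ValueError(
                f"channel (depth {self.vessel_depth} mm + bore + wall) does not "
                f"fit in a {self.block_mm[2]} mm thick block"
            )

    @property
    def channel_center_z(self) -> float:
        """z of the channel axis (negative, below the top surface)."""
        return -(self.vessel_depth + self.wall_thickness + self.channel_diameter / 2)


@dataclass(frozen=True)
class ActuatorSpec:
    """Disk heater on the top surface, centered over the channel axis."""

    diameter: float = 3.5  # mm
    power_mw: float = 56.7

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("actuator diameter must be positive")
        if self.power_mw < 0:
            raise ValueError("actuator power must be nonnegative")

    @property
    def power_density(self) -> float:
        """Areal power density in mW/mm^2."""
        from .solver import power_density

        return power_density(self.power_mw, self.diameter)


@dataclass(frozen=True)
class SensorLayout:
    """Six-thermistor layout: up/down/reference in two vertical layers.

    Upstream/downstream thermistors sit at +/- ``lateral_offset`` from the
    actuator center along the flow axis; the per-layer reference sits at the
    same distance but perpendicular to the flow axis, off the vessel track.
    The bottom layer lies on the top surface (z = 0); the top layer is
    elevated by ``interlayer_spacing`` in the air gap.
    """

    lateral_offset: float = 3.5  # mm, "L"
    interlayer_spacing: float = 1.5  # mm, "H"

    def __post_init__(self) -> None:
        if self.lateral_offset <= 0 or self.interlayer_spacing <= 0:
            raise ValueError("layout distances must be positive")

    def validate_against(self, actuator: ActuatorSpec) -> None:
        if self.lateral_offset <= actuator.diameter / 2:
            raise ValueError(
                "thermistors must sit outside the actuator footprint "
                f"(L={self.lateral_offset} <= D/2={actuator.diameter / 2})"
            )


@dataclass(frozen=True)
class AmbientConditions:
    """Thermal boundary conditions around the phantom.

    ``bottom_surface_temperature`` may be None for an insulated bottom
    (then a positive convective coefficient must anchor the problem).
    """

    ambient_temperature: float = 25.0  # deg C
    convective_coefficient: float = 15.0  # W/(m^2 K), exposed top surface
    bottom_surface_temperature: Optional[float] = 25.0  # deg C, fixed
    inlet_fluid_temperature: float = 25.0  # deg C

    def __post_init__(self) -> None:
        if self.convective_coefficient < 0:
            raise ValueError("convective coefficient must be nonnegative")


@dataclass(frozen=True)
class FlowCondition:
    """Prescribed axial velocity in the channel."""

    mean_speed: float = 1.0  # mm/s
    profile: str = "plug"  # "plug" or "parabolic"

    def __post_init__(self) -> None:
        if self.mean_speed < 0:
            raise ValueError("flow speed must be nonnegative")
        if self.profile not in ("plug", "parabolic"):
            raise ValueError("profile must be 'plug' or 'parabolic'")


@dataclass(frozen=True)
class Scenario:
    """Complete forward-model configuration for one condition."""

    geometry: PhantomGeometry = field(default_factory=PhantomGeometry)
    actuator: ActuatorSpec = field(default_factory=ActuatorSpec)
    layout: SensorLayout = field(default_factory=SensorLayout)
    ambient: AmbientConditions = field(default_factory=AmbientConditions)
    flow: FlowCondition = field(default_factory=FlowCondition)
    spacing: float = 0.5  # mm, uniform grid spacing
    materials: tuple[tuple[str, MaterialProperties], ...] = ()

    def __post_init__(self) -> None:
        self.layout.validate_against(self.actuator)
        if not self.materials:
            object.__setattr__(
                self, "materials", tuple(default_materials().items())
            )

    @property
    def material_map(self) -> dict[str, MaterialProperties]:
        return dict(self.materials)

    def with_(self, **kwargs) -> "Scenario":
        """Return a copy with selected top-level blocks replaced."""
        return replace(self, **kwargs)

    def cache_key(self) -> tuple:
        """Hashable identity of everything the steady solve depends on."""
        mats = tuple(
            (n, m.thermal_conductivity, m.specific_heat, m.density)
            for n, m in self.materials
        )
        return (
            self.geometry,
            self.actuator,
            self.layout,
            self.ambient,
            self.flow,
            self.spacing,
            mats,
        )


def default_scenario(**overrides) -> Scenario:
    """Benchtop reference configuration: D=3.5 mm, P=56.7 mW, L=3.5 mm,
    H=1.5 mm, 2.5-mm channel, 25 degC boundaries, plug flow."""
    return Scenario(**overrides)
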