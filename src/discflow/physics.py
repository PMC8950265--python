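"""Rotational-frame hydraulics for membrane-embedded centrifugal discs.

Pure, stateless functions in SI units. A spinning disc generates a
pseudo-gravitational body force ``rho * r * omega**2`` on a fluid plug; the
resulting hydraulic pressure head drives flow through a connecting channel
(Hagen-Poiseuille) and orthogonally through an embedded porous membrane
(Darcy). Unit conversions from rpm / mm / uL / cP happen only at I/O
boundaries (:mod:`discflow.config`); everything here is kg-m-s.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

__all__ = [
    "Fluid",
    "Membrane",
    "DiscGeometry",
    "FluidPlug",
    "STANDARD_GRAVITY",
    "rpm_to_omega",
    "omega_to_rpm",
    "rcf",
    "centrifugal_force_density",
    "hydraulic_pressure",
    "mean_velocity",
    "discharge",
    "lucas_washburn_length",
    "darcy_flow",
    "hydraulic_resistances",
]

#: Standard gravity used for relative-centrifugal-force conversion (m/s^2).
STANDARD_GRAVITY = 9.81


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class Fluid:
    """A liquid sample.

    Parameters
    ----------
    density : float
        Mass density rho (kg/m^3).
    viscosity : float
        Dynamic viscosity eta (Pa s).
    matrix_factor : float
        Dimensionless multiplier applied to membrane permeability for this
        sample matrix. Encodes osmotic swelling/de-swelling of cellulosic
        fibres by the matrix as a single scalar (>1: de-swollen, more
        permeable; <1: swollen, less permeable).
    """

    name: str
    density: float
    viscosity: float
    matrix_factor: float = 1.0

    def __post_init__(self) -> None:
        _require(self.density > 0, f"density must be > 0, got {self.density}")
        _require(self.viscosity > 0, f"viscosity must be > 0, got {self.viscosity}")
        _require(
            self.matrix_factor > 0,
            f"matrix_factor must be > 0, got {self.matrix_factor}",
        )


@dataclass(frozen=True)
class Membrane:
    """A porous membrane embedded across the orthogonal-flow (OF) port.

    The membrane is modelled as a lumped Darcy resistance: flow crosses its
    thin axis (``thickness``) over the OF-port area (``wetted_area``). A dry
    membrane blocks flow until the transmembrane pressure first exceeds
    ``entry_pressure`` (pressure-sensitive valve).
    """

    name: str
    pore_radius: float
    permeability: float
    entry_pressure: float
    thickness: float
    wetted_area: float
    contact_angle: float = 0.0
    surface_tension: float = 0.072

    def __post_init__(self) -> None:
        _require(self.pore_radius > 0, "pore_radius must be > 0")
        _require(self.permeability > 0, "permeability must be > 0")
        _require(self.entry_pressure >= 0, "entry_pressure must be >= 0")
        _require(self.thickness > 0, "thickness must be > 0")
        _require(self.wetted_area > 0, "wetted_area must be > 0")
        _require(
            0.0 <= self.contact_angle < math.pi,
            f"contact_angle must be in [0, pi), got {self.contact_angle}",
        )
        _require(self.surface_tension > 0, "surface_tension must be > 0")


@dataclass(frozen=True)
class DiscGeometry:
    """Radial layout of one testing domain on the disc.

    All radii are measured from the centre of rotation (CoR). The sample
    chamber ends at ``r_chamber_outer``; a channel of hydraulic diameter
    ``channel_hydraulic_diameter`` and length ``channel_length`` connects it
    to the OF port at ``r_membrane``.
    """

    r_chamber_outer: float
    chamber_area: float
    r_membrane: float
    channel_hydraulic_diameter: float
    channel_length: float
    channel_area: float

    def __post_init__(self) -> None:
        _require(self.r_chamber_outer > 0, "r_chamber_outer must be > 0")
        _require(self.r_membrane > 0, "r_membrane must be > 0")
        _require(
            self.r_chamber_outer <= self.r_membrane,
            "chamber bottom must lie at or inside the membrane radius",
        )
        _require(self.chamber_area > 0, "chamber_area must be > 0")
        _require(self.channel_hydraulic_diameter > 0, "channel_hydraulic_diameter must be > 0")
        _require(self.channel_length > 0, "channel_length must be > 0")
        _require(self.channel_area > 0, "channel_area must be > 0")

    @property
    def chamber_capacity_height(self) -> float:
        """Maximum fluid-column height the chamber can hold is not bounded
        here; callers bound it by the loaded volume."""
        return self.r_chamber_outer


@dataclass(frozen=True)
class FluidPlug:
    """A contiguous fluid column between two radial positions.

    ``r_meniscus`` is the inner (top) end, ``r_bottom`` the outer end.
    """

    r_meniscus: float
    r_bottom: float

    def __post_init__(self) -> None:
        _require(
            self.r_meniscus <= self.r_bottom,
            f"r_meniscus ({self.r_meniscus}) must be <= r_bottom ({self.r_bottom})",
        )

    @property
    def delta_r(self) -> float:
        """Radial extent of the plug (m)."""
        return self.r_bottom - self.r_meniscus

    @property
    def r_bar(self) -> float:
        """Mean radial distance of the plug from the CoR (m)."""
        return 0.5 * (self.r_meniscus + self.r_bottom)


# ---------------------------------------------------------------------------
# Rotation and pressure generation
# ---------------------------------------------------------------------------


def rpm_to_omega(rpm: float) -> float:
    """Convert rotations per minute to angular frequency (rad/s)."""
    _require(rpm >= 0, f"rpm must be >= 0, got {rpm}")
    return rpm * 2.0 * math.pi / 60.0


def omega_to_rpm(omega: float) -> float:
    """Convert angular frequency (rad/s) to rotations per minute."""
    _require(omega >= 0, f"omega must be >= 0, got {omega}")
    return omega * 60.0 / (2.0 * math.pi)


def rcf(rpm: float, r: float, g: float = STANDARD_GRAVITY) -> float:
    """Relative centrifugal force omega^2 r / g in multiples of g.

    At 500 rpm and r = 5.0 cm this is ~14 g; at 4000 rpm, ~894 g.
    """
    _require(r > 0, f"radial distance must be > 0, got {r}")
    omega = rpm_to_omega(rpm)
    return omega * omega * r / g


def centrifugal_force_density(fluid: Fluid, r: float, omega: float) -> float:
    """Centrifugal body force per unit volume, rho r omega^2 (N/m^3)."""
    _require(r >= 0, f"radial distance must be >= 0, got {r}")
    return fluid.density * r * omega * omega


def hydraulic_pressure(fluid: Fluid, plug: FluidPlug, omega: float) -> float:
    """Rotationally induced pressure head rho rbar dr omega^2 (Pa).

    Algebraically equal to ``rho omega^2 (r_bottom^2 - r_meniscus^2) / 2``.
    """
    return fluid.density * plug.r_bar * plug.delta_r * omega * omega


def mean_velocity(
    fluid: Fluid, geom: DiscGeometry, plug: FluidPlug, omega: float
) -> float:
    """Mean channel velocity Dh^2 rho omega^2 rbar dr / (32 eta L) (m/s)."""
    dh = geom.channel_hydraulic_diameter
    return (
        dh * dh * hydraulic_pressure(fluid, plug, omega)
        / (32.0 * fluid.viscosity * geom.channel_length)
    )


def discharge(v_mean: float, area: float) -> float:
    """Volumetric flow rate Q = v A (m^3/s)."""
    _require(area > 0, f"area must be > 0, got {area}")
    return v_mean * area


# ---------------------------------------------------------------------------
# Capillary / porous-medium transport
# ---------------------------------------------------------------------------


def lucas_washburn_length(membrane: Membrane, fluid: Fluid, t: float) -> float:
    """Capillary penetration depth into a dry porous medium (m).

    Lucas-Washburn: ``l(t) = sqrt(gamma r cos(theta) t / (2 eta))``. Applies
    to the initially dry membrane only; a non-wetting contact angle
    (cos(theta) < 0) gives zero penetration with a warning.
    """
    _require(t >= 0, f"time must be >= 0, got {t}")
    cos_theta = math.cos(membrane.contact_angle)
    if cos_theta < 0:
        warnings.warn(
            f"membrane {membrane.name!r} is non-wetting "
            f"(contact angle {membrane.contact_angle:.3f} rad); "
            "no capillary penetration",
            stacklevel=2,
        )
        return 0.0
    return math.sqrt(
        membrane.surface_tension * membrane.pore_radius * cos_theta * t
        / (2.0 * fluid.viscosity)
    )


def darcy_flow(membrane: Membrane, fluid: Fluid, delta_p: float) -> float:
    """Darcy volumetric flow through the wetted membrane (m^3/s).

    ``Q = kappa_eff A_wetted dP / (eta thickness)`` with
    ``kappa_eff = kappa * matrix_factor``.
    """
    _require(delta_p >= 0, f"delta_p must be >= 0, got {delta_p}")
    kappa_eff = membrane.permeability * fluid.matrix_factor
    return kappa_eff * membrane.wetted_area * delta_p / (
        fluid.viscosity * membrane.thickness
    )


def hydraulic_resistances(
    geom: DiscGeometry, membrane: Membrane, fluid: Fluid
) -> tuple[float, float]:
    """Series hydraulic resistances (Pa s/m^3) of channel and membrane.

    ``R_channel = 32 eta L / (Dh^2 A_channel)`` (Hagen-Poiseuille lumped) and
    ``R_membrane = eta thickness / (kappa_eff A_wetted)`` (Darcy lumped), so
    that Q = dP / (R_channel + R_membrane) for the series path.
    """
    dh = geom.channel_hydraulic_diameter
    r_channel = 32.0 * fluid.viscosity * geom.channel_length / (dh * dh * geom.channel_area)
    kappa_eff = membrane.permeability * fluid.matrix_factor
    r_membrane = fluid.viscosity * membrane.thickness / (kappa_eff * membrane.wetted_area)
    return r_channel, r_membrane
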