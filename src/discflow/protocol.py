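"""Spin-protocol construction.

Two kinds of protocols are produced: stepped speed sweeps as used on real
spin controllers, and compensating protocols that raise the spin speed as
the column drains so the hydraulic head (hence the discharge) stays constant.

For the compensating protocol the problem has a closed form: holding the
head at dP* makes the discharge Q = dP* / (R_channel + R_membrane) constant,
so the meniscus advances linearly, ``r_men(t) = r_men(0) + (Q / A) t``, and
the required speed is

    omega(t) = sqrt( 2 dP* / (rho (r_membrane^2 - r_men(t)^2)) ),

which rises monotonically as the chamber empties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .physics import (
    DiscGeometry,
    Fluid,
    FluidPlug,
    Membrane,
    hydraulic_resistances,
    omega_to_rpm,
)
from .simulate import SpinProtocol

__all__ = ["ProtocolTarget", "DesignedProtocol", "design_protocol", "stepped_sweep"]


@dataclass(frozen=True)
class ProtocolTarget:
    """Target for a compensating protocol.

    ``mode`` selects whether ``target_value`` is a pressure head (Pa) or a
    discharge (m^3/s); the two are equivalent up to the series resistance.
    """

    mode: Literal["constant_pressure", "constant_discharge"]
    target_value: float
    horizon: float
    max_rpm: float = 6000.0
    step_duration: float | None = None

    def __post_init__(self) -> None:
        if self.target_value <= 0:
            raise ValueError("target_value must be > 0")
        if self.horizon <= 0:
            raise ValueError("horizon must be > 0")
        if self.max_rpm <= 0:
            raise ValueError("max_rpm must be > 0")
        if self.step_duration is not None and self.step_duration <= 0:
            raise ValueError("step_duration must be > 0")


@dataclass(frozen=True)
class DesignedProtocol:
    """A designed protocol plus its design metadata."""

    protocol: SpinProtocol
    target_pressure: float
    target_discharge: float
    drain_time: float
    truncated_at_max_rpm: bool


def _required_rpm(
    fluid: Fluid, r_membrane: float, r_men: float, dp: float
) -> float:
    span = r_membrane * r_membrane - r_men * r_men
    if span <= 0:
        raise ValueError("plug has no radial extent; pressure target unreachable")
    return omega_to_rpm(math.sqrt(2.0 * dp / (fluid.density * span)))


def design_protocol(
    geom: DiscGeometry,
    fluid: Fluid,
    membrane: Membrane,
    initial_plug: FluidPlug,
    target: ProtocolTarget,
    n_samples: int = 400,
) -> DesignedProtocol:
    """Design a spin protocol holding pressure (or discharge) constant.

    The plug spans the meniscus to the membrane (primed channel). Returns a
    sampled, linearly interpolated protocol, or a stepped one when
    ``target.step_duration`` is set (each step uses the speed correct for the
    plug state at the step midpoint). The schedule is truncated, and flagged,
    once the required speed reaches ``target.max_rpm``.

    Raises
    ------
    ValueError
        If the target cannot be met at t = 0 under ``max_rpm`` (the error
        names the minimum feasible target) or the entry pressure exceeds the
        target head (flow would never start).
    """
    r_ch, r_mem = hydraulic_resistances(geom, membrane, fluid)
    r_total = r_ch + r_mem
    if target.mode == "constant_pressure":
        dp = target.target_value
    else:
        dp = target.target_value * r_total
    q = dp / r_total

    if dp < membrane.entry_pressure:
        raise ValueError(
            f"target head {dp:.6g} Pa is below the membrane entry pressure "
            f"{membrane.entry_pressure:.6g} Pa; flow would never start"
        )
    rpm0 = _required_rpm(fluid, geom.r_membrane, initial_plug.r_meniscus, dp)
    if rpm0 > target.max_rpm:
        span0 = geom.r_membrane**2 - initial_plug.r_meniscus**2
        omega_max = target.max_rpm * 2 * math.pi / 60.0
        dp_max = 0.5 * fluid.density * omega_max**2 * span0
        raise ValueError(
            f"target requires {rpm0:.0f} rpm at t=0 (cap {target.max_rpm:.0f}); "
            f"maximum feasible head is {dp_max:.6g} Pa"
        )

    # constant discharge -> meniscus moves linearly until the chamber empties
    dr0_chamber = geom.r_chamber_outer - initial_plug.r_meniscus
    t_empty = geom.chamber_area * dr0_chamber / q
    t_end = min(target.horizon, t_empty)

    def men_at(t: float) -> float:
        return min(
            initial_plug.r_meniscus + q * t / geom.chamber_area,
            geom.r_chamber_outer,
        )

    truncated = False
    if target.step_duration is None:
        ts = np.linspace(0.0, t_end, n_samples)
        rpms = np.array([_required_rpm(fluid, geom.r_membrane, men_at(t), dp) for t in ts])
        if rpms[-1] > target.max_rpm:
            truncated = True
            last = int(np.searchsorted(rpms, target.max_rpm))
            ts, rpms = ts[: last + 1], np.minimum(rpms[: last + 1], target.max_rpm)
            if len(ts) < 2:
                ts = np.array([0.0, 1e-6])
                rpms = np.array([rpms[0], rpms[0]])
        protocol = SpinProtocol(times=tuple(ts), rpms=tuple(rpms), interpolate=True)
    else:
        steps = []
        t = 0.0
        while t < t_end - 1e-12:
            d = min(target.step_duration, t_end - t)
            mid = men_at(t + 0.5 * d)
            rpm = _required_rpm(fluid, geom.r_membrane, mid, dp)
            if rpm > target.max_rpm:
                truncated = True
                break
            steps.append((d, rpm))
            t += d
        if not steps:
            raise ValueError("max_rpm reached before the first step completed")
        protocol = SpinProtocol(steps=tuple(steps))

    return DesignedProtocol(
        protocol=protocol,
        target_pressure=dp,
        target_discharge=q,
        drain_time=t_empty,
        truncated_at_max_rpm=truncated,
    )


def stepped_sweep(
    start_rpm: float, end_rpm: float, increment_rpm: float, step_duration: float
) -> SpinProtocol:
    """Piecewise-constant sweep from ``start_rpm`` to ``end_rpm``.

    Speeds rise by ``increment_rpm`` per step; if the range is not an exact
    multiple of the increment the final step is clamped to ``end_rpm``.
    """
    if increment_rpm <= 0:
        raise ValueError("increment_rpm must be > 0")
    if end_rpm < start_rpm:
        raise ValueError("end_rpm must be >= start_rpm")
    if step_duration <= 0:
        raise ValueError("step_duration must be > 0")
    rpms = []
    r = start_rpm
    while r < end_rpm - 1e-9:
        rpms.append(r)
        r += increment_rpm
    rpms.append(end_rpm)
    return SpinProtocol(steps=tuple((step_duration, r) for r in rpms))
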