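"""Synthetic graduation-crossing observations.

Emulates a stroboscopic-videography drainage study: a chamber carries 1 mm
graduation marks, and the elapsed time at which the receding meniscus crosses
each mark is recorded. The generator simulates drainage per replicate, reads
crossing times off the profile, and applies two noise sources seen in real
studies: per-replicate membrane-permeability variation (lognormal, from the
non-uniform 3D pore network of membrane cutouts) and timing jitter on the
recorded crossings (Gaussian). Sample-matrix composition enters as a
permeability multiplier on the membrane (osmotic de-swelling raises
permeability; swelling lowers it).

All randomness flows through an explicit seed; the true per-replicate
parameters are retained in a sidecar so that estimator recovery can be
checked against the values that generated the data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .physics import DiscGeometry, Fluid, FluidPlug, Membrane
from .simulate import (
    DrainageProfile,
    SolverOptions,
    SpinProtocol,
    entry_threshold_rpm,
    rpm_to_omega,
    simulate_drainage,
    theoretical_decay_constant,
)

__all__ = [
    "NoiseModel",
    "StudyDesign",
    "DrainageObservations",
    "generate_observations",
    "generate_study",
]

OBS_COLUMNS = [
    "replicate_id",
    "membrane",
    "matrix",
    "rpm",
    "graduation_height_m",
    "crossing_time_s",
    "no_flow",
]


@dataclass(frozen=True)
class NoiseModel:
    """Observation noise. ``timing_sd`` jitters crossing times (s);
    ``permeability_cv`` is the lognormal coefficient of variation of the
    per-replicate membrane permeability."""

    timing_sd: float = 0.05
    permeability_cv: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.timing_sd < 0:
            raise ValueError("timing_sd must be >= 0")
        if self.permeability_cv < 0:
            raise ValueError("permeability_cv must be >= 0")


@dataclass(frozen=True)
class StudyDesign:
    """Factorial drainage study: membranes x matrices x spin speeds, with
    ``replicates`` trials per condition, each loading ``sample_volume`` and
    read against graduations ``graduation_spacing`` apart."""

    membranes: tuple[Membrane, ...]
    matrices: tuple[Fluid, ...]
    rpms: tuple[float, ...]
    replicates: int = 4
    sample_volume: float = 200e-9
    graduation_spacing: float = 1e-3

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.graduation_spacing <= 0:
            raise ValueError("graduation_spacing must be > 0")
        if not self.rpms:
            raise ValueError("rpm list must be non-empty")
        if not self.membranes or not self.matrices:
            raise ValueError("membranes and matrices must be non-empty")
        object.__setattr__(self, "membranes", tuple(self.membranes))
        object.__setattr__(self, "matrices", tuple(self.matrices))
        object.__setattr__(self, "rpms", tuple(float(r) for r in self.rpms))


@dataclass(frozen=True)
class DrainageObservations:
    """Observation table plus the true-parameter sidecar.

    ``table`` columns: replicate_id, membrane, matrix, rpm,
    graduation_height_m, crossing_time_s, no_flow. The ``sidecar`` maps
    replicate_id -> dict with the drawn permeability, effective permeability
    (matrix factor applied), the decay constant of the replicate's noiseless
    crossings, and the seed.
    """

    table: pd.DataFrame
    sidecar: dict

    def __post_init__(self) -> None:
        missing = [c for c in OBS_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"observation table missing columns: {missing}")


def _graduation_levels(delta_r0: float, spacing: float) -> np.ndarray:
    """Graduation heights strictly below the initial column, descending."""
    n = int(math.floor((delta_r0 - 1e-12) / spacing))
    return delta_r0 - spacing * np.arange(1, n + 1)


def _noiseless_crossings(
    profile: DrainageProfile, levels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Interpolated crossing times for the levels the profile reaches."""
    reached = levels >= profile.delta_r[-1] - 1e-12
    lv = levels[reached]
    t = np.interp(-lv, -profile.delta_r, profile.times)
    return lv, t


def generate_observations(
    profile: DrainageProfile,
    spacing: float,
    noise: NoiseModel,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Graduation crossings for a single replicate's profile.

    Crossing times are linearly interpolated from the profile at each
    graduation level below the initial column height, then perturbed with
    Gaussian timing noise and re-sorted so times still increase as the
    column falls. Deterministic given the noise seed.
    """
    rng = rng if rng is not None else np.random.default_rng(noise.seed)
    dr0 = profile.initial_height
    levels = _graduation_levels(dr0, spacing)
    if levels.size == 0:
        warnings.warn(
            "graduation spacing exceeds the initial column height; "
            "no observations generated",
            stacklevel=2,
        )
        return pd.DataFrame(
            {"graduation_height_m": [], "crossing_time_s": []}, dtype=float
        )
    levels, t_true = _noiseless_crossings(profile, levels)
    t_obs = t_true + rng.normal(0.0, noise.timing_sd, size=t_true.shape)
    # graduations are read in the order crossed; sorting restores the
    # physically required monotonicity that jitter may break
    t_obs = np.sort(np.maximum(t_obs, 0.0))
    return pd.DataFrame(
        {"graduation_height_m": levels, "crossing_time_s": t_obs}
    )


def _fit_k_noiseless(levels: np.ndarray, times: np.ndarray) -> float:
    """Decay constant of the noiseless crossings (semilog OLS slope)."""
    t = times - times[0]
    y = np.log(levels)
    slope = np.polyfit(t, y, 1)[0]
    return -float(slope)


def generate_study(
    design: StudyDesign,
    geom: DiscGeometry,
    noise: NoiseModel,
    protocol_duration: float | None = None,
    solver_options: SolverOptions | None = None,
) -> DrainageObservations:
    """Run the full factorial drainage study.

    For each membrane x matrix x rpm condition and replicate, a replicate
    permeability is drawn (lognormal around the membrane's nominal value,
    CV = ``noise.permeability_cv``), the matrix factor is applied, drainage
    is simulated at constant speed until the chamber empties, and graduation
    crossings are emitted. Conditions whose speed cannot wet the membrane
    are flagged ``no_flow`` rather than dropped.
    """
    rng = np.random.default_rng(noise.seed)
    solver_options = solver_options or SolverOptions()
    rows: list[pd.DataFrame] = []
    sidecar: dict = {"seed": noise.seed, "replicates": {}}
    dr0 = design.sample_volume / geom.chamber_area
    plug0 = FluidPlug(geom.r_chamber_outer - dr0, geom.r_membrane)
    cv = noise.permeability_cv
    sigma = math.sqrt(math.log(1.0 + cv * cv)) if cv > 0 else 0.0

    for membrane in design.membranes:
        for fluid in design.matrices:
            for rpm in design.rpms:
                threshold = entry_threshold_rpm(geom, fluid, membrane, plug0)
                for rep in range(design.replicates):
                    rep_id = f"{membrane.name}|{fluid.name}|{int(rpm)}|r{rep}"
                    # lognormal with unit mean and the requested CV
                    mult = (
                        math.exp(rng.normal(-0.5 * sigma * sigma, sigma))
                        if sigma > 0
                        else 1.0
                    )
                    kappa_rep = membrane.permeability * mult
                    mem_rep = Membrane(
                        name=membrane.name,
                        pore_radius=membrane.pore_radius,
                        permeability=kappa_rep,
                        entry_pressure=membrane.entry_pressure,
                        thickness=membrane.thickness,
                        wetted_area=membrane.wetted_area,
                        contact_angle=membrane.contact_angle,
                        surface_tension=membrane.surface_tension,
                    )
                    if rpm < threshold:
                        rows.append(
                            pd.DataFrame(
                                {
                                    "replicate_id": [rep_id],
                                    "membrane": [membrane.name],
                                    "matrix": [fluid.name],
                                    "rpm": [rpm],
                                    "graduation_height_m": [np.nan],
                                    "crossing_time_s": [np.nan],
                                    "no_flow": [True],
                                }
                            )
                        )
                        sidecar["replicates"][rep_id] = {
                            "permeability_m2": kappa_rep,
                            "permeability_eff_m2": kappa_rep * fluid.matrix_factor,
                            "true_k_per_s": None,
                            "no_flow": True,
                        }
                        continue
                    if protocol_duration is None:
                        k_guess = theoretical_decay_constant(
                            geom, fluid, mem_rep, rpm_to_omega(rpm), plug0.r_bar
                        )
                        duration = min(15.0 / k_guess, 5e4)
                    else:
                        duration = protocol_duration
                    profile = simulate_drainage(
                        geom,
                        fluid,
                        mem_rep,
                        SpinProtocol.constant(rpm, duration),
                        design.sample_volume,
                        solver_options,
                    )
                    levels = _graduation_levels(dr0, design.graduation_spacing)
                    lv, t_true = _noiseless_crossings(profile, levels)
                    obs = generate_observations(
                        profile, design.graduation_spacing, noise, rng
                    )
                    obs.insert(0, "replicate_id", rep_id)
                    obs.insert(1, "membrane", membrane.name)
                    obs.insert(2, "matrix", fluid.name)
                    obs.insert(3, "rpm", rpm)
                    obs["no_flow"] = False
                    rows.append(obs)
                    sidecar["replicates"][rep_id] = {
                        "permeability_m2": kappa_rep,
                        "permeability_eff_m2": kappa_rep * fluid.matrix_factor,
                        "true_k_per_s": _fit_k_noiseless(lv, t_true),
                        "no_flow": False,
                    }

    table = pd.concat(rows, ignore_index=True)[OBS_COLUMNS]
    return DrainageObservations(table=table, sidecar=sidecar)
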