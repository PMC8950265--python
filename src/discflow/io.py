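"""File round-trips for profiles, observations, fits and protocols.

Inside the library everything is SI; files use the bench units the numbers
are read in (mm, microlitres, rpm, seconds). Every reader accepts its own
writer's output. Numeric CSV output is written at 9 significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .observe import OBS_COLUMNS, DrainageObservations
from .simulate import DrainageProfile, SpinProtocol

__all__ = [
    "write_profile",
    "read_profile",
    "write_observations",
    "read_observations",
    "write_fits",
    "write_summary",
    "write_protocol_csv",
    "read_protocol_csv",
    "write_protocol_json",
    "read_protocol_json",
]

FLOAT_FMT = "%.9g"


def write_profile(profile: DrainageProfile, path: str | Path) -> None:
    """Write a drainage profile as CSV (mm / uL/s at the file boundary)."""
    df = pd.DataFrame(
        {
            "time_s": profile.times,
            "delta_r_mm": profile.delta_r * 1e3,
            "r_meniscus_mm": profile.r_meniscus * 1e3,
            "q_uL_per_s": profile.q * 1e9,
            "wetted": profile.wetted.astype(int),
        }
    )
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_profile(path: str | Path, chamber_area: float) -> DrainageProfile:
    df = pd.read_csv(path)
    delta_r = df["delta_r_mm"].to_numpy() * 1e-3
    return DrainageProfile(
        times=df["time_s"].to_numpy(),
        delta_r=delta_r,
        r_meniscus=df["r_meniscus_mm"].to_numpy() * 1e-3,
        q=df["q_uL_per_s"].to_numpy() * 1e-9,
        wetted=df["wetted"].to_numpy().astype(bool),
        cumulative_volume=chamber_area * (delta_r[0] - delta_r),
        chamber_area=chamber_area,
    )


def write_observations(
    obs: DrainageObservations, csv_path: str | Path, sidecar_path: str | Path | None = None
) -> None:
    """Observation table as CSV (graduations in mm) plus true-parameter
    sidecar JSON."""
    df = obs.table.copy()
    df["graduation_mm"] = df.pop("graduation_height_m") * 1e3
    df["time_s"] = df.pop("crossing_time_s")
    cols = ["replicate_id", "membrane", "matrix", "rpm", "graduation_mm", "time_s", "no_flow"]
    df[cols].to_csv(csv_path, index=False, float_format=FLOAT_FMT)
    if sidecar_path is not None:
        Path(sidecar_path).write_text(json.dumps(obs.sidecar, indent=1))


def read_observations(
    csv_path: str | Path, sidecar_path: str | Path | None = None
) -> DrainageObservations:
    df = pd.read_csv(csv_path)
    df["graduation_height_m"] = df.pop("graduation_mm") * 1e-3
    df["crossing_time_s"] = df.pop("time_s")
    if "no_flow" not in df.columns:
        df["no_flow"] = False
    sidecar = {}
    if sidecar_path is not None and Path(sidecar_path).exists():
        sidecar = json.loads(Path(sidecar_path).read_text())
    return DrainageObservations(table=df[OBS_COLUMNS], sidecar=sidecar)


def write_fits(fits: pd.DataFrame, path: str | Path) -> None:
    """Per-replicate or per-condition fit table (y0 in mm at the boundary)."""
    df = fits.copy()
    if "y0_m" in df.columns:
        df["y0_mm"] = df.pop("y0_m") * 1e3
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def write_summary(summary: pd.DataFrame, path: str | Path) -> None:
    summary.to_csv(path, index=False, float_format=FLOAT_FMT)


def _protocol_steps(protocol: SpinProtocol) -> list[tuple[float, float]]:
    if protocol.steps is None:
        raise ValueError(
            "only stepped protocols can be written as controller CSV; "
            "sampled protocols round-trip through JSON"
        )
    return list(protocol.steps)


def write_protocol_csv(protocol: SpinProtocol, path: str | Path) -> None:
    """Stepped protocol as controller-importable CSV."""
    steps = _protocol_steps(protocol)
    df = pd.DataFrame(
        {
            "step_index": np.arange(len(steps)),
            "duration_s": [d for d, _ in steps],
            "rpm": [r for _, r in steps],
        }
    )
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_protocol_csv(path: str | Path) -> SpinProtocol:
    df = pd.read_csv(path).sort_values("step_index")
    return SpinProtocol(steps=tuple(zip(df["duration_s"], df["rpm"])))


def write_protocol_json(protocol: SpinProtocol, path: str | Path) -> None:
    if protocol.steps is not None:
        payload = {"steps": [list(s) for s in protocol.steps]}
    else:
        payload = {
            "times": list(protocol.times),
            "rpms": list(protocol.rpms),
            "interpolate": protocol.interpolate,
        }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_protocol_json(path: str | Path) -> SpinProtocol:
    payload = json.loads(Path(path).read_text())
    if "steps" in payload:
        return SpinProtocol(steps=tuple(tuple(s) for s in payload["steps"]))
    return SpinProtocol(
        times=tuple(payload["times"]),
        rpms=tuple(payload["rpms"]),
        interpolate=payload.get("interpolate", True),
    )
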