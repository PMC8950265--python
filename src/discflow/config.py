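"""Run configuration: unit-suffixed YAML/JSON in, validated SI objects out.

Config files carry explicit unit suffixes on every dimensional key
(``r_membrane_mm``, ``viscosity_cP``, ``sample_volume_uL``, ...); the loader
converts to SI and lets the domain types enforce their invariants. Unknown
keys are rejected so typos fail loudly. ``default_config`` is the packaged
reference device: a 70 mm disc domain with the sample chamber just inside
the OF membrane, nitrocellulose membranes of two pore sizes, and three
water-like sample matrices whose composition enters as a permeability
multiplier.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .decay import fit_condition_means, fit_study, relative_permeability, summarize_fits
from .io import write_fits, write_observations, write_summary
from .observe import NoiseModel, StudyDesign, generate_study
from .physics import DiscGeometry, Fluid, Membrane

__all__ = [
    "RunConfig",
    "load_config",
    "write_config",
    "default_config",
    "default_geometry",
    "default_membranes",
    "default_fluids",
    "run_pipeline",
]

logger = logging.getLogger("discflow")

# unit suffix -> factor to SI
_UNIT_FACTORS = {
    "mm": 1e-3,
    "mm2": 1e-6,
    "um": 1e-6,
    "uL": 1e-9,
    "cP": 1e-3,
    "Pa": 1.0,
    "s": 1.0,
    "m2": 1.0,
    "kg_per_m3": 1.0,
    "N_per_m": 1.0,
    "deg": 3.141592653589793 / 180.0,
}


def _from_units(d: dict, prefix: str, allowed: dict[str, float]) -> float:
    """Pop ``<prefix>_<suffix>`` from d for any allowed suffix, return SI."""
    hits = [(suf, f) for suf, f in allowed.items() if f"{prefix}_{suf}" in d]
    if not hits:
        raise ValueError(
            f"missing field {prefix!r}; expected one of "
            + ", ".join(f"{prefix}_{s}" for s in allowed)
        )
    if len(hits) > 1:
        raise ValueError(f"field {prefix!r} given in multiple units")
    suf, factor = hits[0]
    return float(d.pop(f"{prefix}_{suf}")) * factor


def _reject_unknown(d: dict, where: str) -> None:
    if d:
        raise ValueError(f"unknown keys in {where}: {sorted(d)}")


def _geometry_from_dict(d: dict) -> DiscGeometry:
    d = dict(d)
    geom = DiscGeometry(
        r_chamber_outer=_from_units(d, "r_chamber_outer", {"mm": 1e-3, "m": 1.0}),
        chamber_area=_from_units(d, "chamber_area", {"mm2": 1e-6, "m2": 1.0}),
        r_membrane=_from_units(d, "r_membrane", {"mm": 1e-3, "m": 1.0}),
        channel_hydraulic_diameter=_from_units(
            d, "channel_hydraulic_diameter", {"mm": 1e-3, "um": 1e-6, "m": 1.0}
        ),
        channel_length=_from_units(d, "channel_length", {"mm": 1e-3, "m": 1.0}),
        channel_area=_from_units(d, "channel_area", {"mm2": 1e-6, "m2": 1.0}),
    )
    _reject_unknown(d, "geometry")
    return geom


def _fluid_from_dict(d: dict) -> Fluid:
    d = dict(d)
    fluid = Fluid(
        name=str(d.pop("name")),
        density=_from_units(d, "density", {"kg_per_m3": 1.0}),
        viscosity=_from_units(d, "viscosity", {"cP": 1e-3, "Pa_s": 1.0}),
        matrix_factor=float(d.pop("matrix_factor", 1.0)),
    )
    _reject_unknown(d, f"fluid {fluid.name!r}")
    return fluid


def _membrane_from_dict(d: dict) -> Membrane:
    d = dict(d)
    mem = Membrane(
        name=str(d.pop("name")),
        pore_radius=_from_units(d, "pore_radius", {"um": 1e-6, "m": 1.0}),
        permeability=_from_units(d, "permeability", {"m2": 1.0}),
        entry_pressure=_from_units(d, "entry_pressure", {"Pa": 1.0, "kPa": 1e3}),
        thickness=_from_units(d, "thickness", {"um": 1e-6, "mm": 1e-3, "m": 1.0}),
        wetted_area=_from_units(d, "wetted_area", {"mm2": 1e-6, "m2": 1.0}),
        contact_angle=_from_units(d, "contact_angle", {"deg": _UNIT_FACTORS["deg"], "rad": 1.0})
        if any(k.startswith("contact_angle") for k in d)
        else 0.0,
        surface_tension=_from_units(d, "surface_tension", {"N_per_m": 1.0})
        if any(k.startswith("surface_tension") for k in d)
        else 0.072,
    )
    _reject_unknown(d, f"membrane {mem.name!r}")
    return mem


@dataclass(frozen=True)
class RunConfig:
    """Everything a study run needs, in SI."""

    geometry: DiscGeometry
    fluids: tuple[Fluid, ...]
    membranes: tuple[Membrane, ...]
    study: StudyDesign
    noise: NoiseModel
    seed: int
    output_dir: Path = Path("results")


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    text = Path(path).read_text()
    raw = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    raw = dict(raw)
    geometry = _geometry_from_dict(raw.pop("geometry"))
    fluids = tuple(_fluid_from_dict(f) for f in raw.pop("fluids"))
    membranes = tuple(_membrane_from_dict(m) for m in raw.pop("membranes"))
    sd = dict(raw.pop("study"))
    study = StudyDesign(
        membranes=membranes,
        matrices=fluids,
        rpms=tuple(float(r) for r in sd.pop("rpms")),
        replicates=int(sd.pop("replicates", 4)),
        sample_volume=_from_units(sd, "sample_volume", {"uL": 1e-9, "m3": 1.0}),
        graduation_spacing=_from_units(sd, "graduation_spacing", {"mm": 1e-3, "m": 1.0}),
    )
    _reject_unknown(sd, "study")
    nd = dict(raw.pop("noise", {}))
    seed = int(raw.pop("seed"))
    noise = NoiseModel(
        timing_sd=_from_units(nd, "timing_sd", {"s": 1.0}) if any(
            k.startswith("timing_sd") for k in nd
        ) else 0.05,
        permeability_cv=float(nd.pop("permeability_cv", 0.10)),
        seed=seed,
    )
    _reject_unknown(nd, "noise")
    output_dir = Path(raw.pop("output_dir", "results"))
    _reject_unknown(raw, "config")
    return RunConfig(
        geometry=geometry,
        fluids=fluids,
        membranes=membranes,
        study=study,
        noise=noise,
        seed=seed,
        output_dir=output_dir,
    )


def config_to_dict(cfg: RunConfig) -> dict:
    g = cfg.geometry
    return {
        "geometry": {
            "r_chamber_outer_mm": g.r_chamber_outer * 1e3,
            "chamber_area_mm2": g.chamber_area * 1e6,
            "r_membrane_mm": g.r_membrane * 1e3,
            "channel_hydraulic_diameter_mm": g.channel_hydraulic_diameter * 1e3,
            "channel_length_mm": g.channel_length * 1e3,
            "channel_area_mm2": g.channel_area * 1e6,
        },
        "fluids": [
            {
                "name": f.name,
                "density_kg_per_m3": f.density,
                "viscosity_cP": f.viscosity * 1e3,
                "matrix_factor": f.matrix_factor,
            }
            for f in cfg.fluids
        ],
        "membranes": [
            {
                "name": m.name,
                "pore_radius_um": m.pore_radius * 1e6,
                "permeability_m2": m.permeability,
                "entry_pressure_Pa": m.entry_pressure,
                "thickness_um": m.thickness * 1e6,
                "wetted_area_mm2": m.wetted_area * 1e6,
                "contact_angle_rad": m.contact_angle,
                "surface_tension_N_per_m": m.surface_tension,
            }
            for m in cfg.membranes
        ],
        "study": {
            "rpms": list(cfg.study.rpms),
            "replicates": cfg.study.replicates,
            "sample_volume_uL": cfg.study.sample_volume * 1e9,
            "graduation_spacing_mm": cfg.study.graduation_spacing * 1e3,
        },
        "noise": {
            "timing_sd_s": cfg.noise.timing_sd,
            "permeability_cv": cfg.noise.permeability_cv,
        },
        "seed": cfg.seed,
        "output_dir": str(cfg.output_dir),
    }


def write_config(cfg: RunConfig, path: str | Path) -> None:
    payload = config_to_dict(cfg)
    if str(path).endswith(".json"):
        Path(path).write_text(json.dumps(payload, indent=1))
    else:
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


# ---------------------------------------------------------------------------
# Reference device
# ---------------------------------------------------------------------------


def default_geometry() -> DiscGeometry:
    """One testing domain of the reference 70 mm disc: 20 mm^2 sample
    chamber ending 28 mm from the CoR (200 uL -> 10 mm column, ten 1 mm
    graduations), OF port 0.5 mm beyond the chamber bottom, 10 mm serpentine
    channel of 0.5 mm hydraulic diameter."""
    return DiscGeometry(
        r_chamber_outer=28e-3,
        chamber_area=20e-6,
        r_membrane=28.5e-3,
        channel_hydraulic_diameter=0.5e-3,
        channel_length=10e-3,
        channel_area=1e-6,
    )


def default_membranes(include_pvdf: bool = False) -> tuple[Membrane, ...]:
    """Nitrocellulose membranes of two nominal pore sizes; optionally a
    hydrophobic PVDF membrane whose high entry pressure blocks flow over the
    study's speed range."""
    nc02 = Membrane(
        name="nc_0.2um",
        pore_radius=0.2e-6,
        permeability=1e-14,
        entry_pressure=500.0,
        thickness=150e-6,
        wetted_area=3.14e-6,
    )
    nc045 = Membrane(
        name="nc_0.45um",
        pore_radius=0.45e-6,
        permeability=2.5e-14,
        entry_pressure=300.0,
        thickness=150e-6,
        wetted_area=3.14e-6,
    )
    mems = [nc02, nc045]
    if include_pvdf:
        mems.append(
            Membrane(
                name="pvdf_0.2um",
                pore_radius=0.2e-6,
                permeability=1e-14,
                entry_pressure=60e3,
                thickness=150e-6,
                wetted_area=3.14e-6,
                contact_angle=2.1,
            )
        )
    return tuple(mems)


def default_fluids() -> tuple[Fluid, ...]:
    """Water-like sample matrices. Matrix composition acts on membrane
    permeability (osmotic de-swelling of the cellulosic fibres): urine >
    buffer > plasma."""
    return (
        Fluid(name="artificial_urine", density=1000.0, viscosity=1e-3, matrix_factor=1.3),
        Fluid(name="assay_buffer", density=1000.0, viscosity=1e-3, matrix_factor=1.0),
        Fluid(name="artificial_plasma", density=1000.0, viscosity=1e-3, matrix_factor=0.6),
    )


def default_config(seed: int = 1, output_dir: str | Path = "results") -> RunConfig:
    """The default emulated drainage study: 750-2000 rpm in 250 rpm steps,
    n = 4 replicates, 200 uL samples, 1 mm graduations, timing jitter 0.05 s
    and 10% replicate permeability CV."""
    membranes = default_membranes()
    fluids = default_fluids()
    study = StudyDesign(
        membranes=membranes,
        matrices=fluids,
        rpms=tuple(range(750, 2001, 250)),
        replicates=4,
        sample_volume=200e-9,
        graduation_spacing=1e-3,
    )
    return RunConfig(
        geometry=default_geometry(),
        fluids=fluids,
        membranes=membranes,
        study=study,
        noise=NoiseModel(timing_sd=0.05, permeability_cv=0.10, seed=seed),
        seed=seed,
        output_dir=Path(output_dir),
    )


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def run_pipeline(cfg: RunConfig, reference_matrix: str | None = None) -> dict:
    """Generate the study, fit decays, summarize, and write all artifacts.

    Returns a dict with the in-memory tables and the paths written.
    Deterministic given the config seed.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = {}

    t0 = time.perf_counter()
    obs = generate_study(cfg.study, cfg.geometry, cfg.noise)
    stages["generate_s"] = time.perf_counter() - t0
    logger.info("generated %d observation rows (seed=%d, %.2fs)",
                len(obs.table), cfg.seed, stages["generate_s"])
    write_observations(obs, out / "observations.csv", out / "observations_sidecar.json")

    t0 = time.perf_counter()
    fits = fit_study(obs.table, method="semilog")
    mean_fits = fit_condition_means(obs.table, method="semilog")
    summary = summarize_fits(fits)
    stages["fit_s"] = time.perf_counter() - t0
    logger.info("fitted %d replicates, %d conditions (%.2fs)",
                len(fits), len(mean_fits), stages["fit_s"])
    write_fits(fits, out / "fits.csv")
    write_fits(mean_fits, out / "fits_condition_means.csv")
    write_summary(summary, out / "summary.csv")

    result = {
        "observations": obs,
        "fits": fits,
        "condition_mean_fits": mean_fits,
        "summary": summary,
        "paths": [
            out / "observations.csv",
            out / "observations_sidecar.json",
            out / "fits.csv",
            out / "fits_condition_means.csv",
            out / "summary.csv",
        ],
        "timings": stages,
    }
    if reference_matrix is not None:
        factors = relative_permeability(fits, reference_matrix)
        factors.to_csv(out / "matrix_factors.csv", header=True)
        result["matrix_factors"] = factors
        result["paths"].append(out / "matrix_factors.csv")
    return result
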