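import pytest

from discflow import (
    FluidPlug,
    NoiseModel,
    StudyDesign,
    default_config,
    default_fluids,
    default_geometry,
    default_membranes,
    generate_study,
)


@pytest.fixture(scope="session")
def geom():
    return default_geometry()


@pytest.fixture(scope="session")
def buffer_fluid():
    return default_fluids()[1]  # assay buffer, matrix_factor 1


@pytest.fixture(scope="session")
def nc_membrane():
    return default_membranes()[0]  # 0.2 um nitrocellulose


@pytest.fixture(scope="session")
def pvdf_membrane():
    return default_membranes(include_pvdf=True)[2]


@pytest.fixture(scope="session")
def initial_plug(geom):
    dr0 = 200e-9 / geom.chamber_area
    return FluidPlug(geom.r_chamber_outer - dr0, geom.r_membrane)


@pytest.fixture(scope="session")
def default_study_obs(geom):
    """The full default drainage study at a fixed seed (shared: ~2 s)."""
    cfg = default_config(seed=1)
    return generate_study(cfg.study, geom, cfg.noise)


@pytest.fixture(scope="session")
def small_study_obs(geom, nc_membrane, buffer_fluid):
    """A two-speed, two-replicate study for cheap structural checks."""
    design = StudyDesign(
        membranes=(nc_membrane,),
        matrices=(buffer_fluid,),
        rpms=(1000.0, 1500.0),
        replicates=2,
        sample_volume=200e-9,
        graduation_spacing=1e-3,
    )
    return design, generate_study(design, geom, NoiseModel(seed=11))
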