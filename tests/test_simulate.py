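"""Drainage ODE: oracle equivalence, valving, conservation, monotonicity."""

import numpy as np
import pytest

from discflow import (
    FluidPlug,
    SolverOptions,
    SpinProtocol,
    closed_form_drainage,
    entry_threshold_rpm,
    hydraulic_pressure,
    rpm_to_omega,
    simulate_drainage,
    theoretical_decay_constant,
)

VOLUME = 200e-9


def test_closed_form_values():
    assert closed_form_drainage(0.01, 0.02, [0.0])[0] == pytest.approx(0.02)
    assert np.allclose(closed_form_drainage(0.0, 0.02, [0, 50, 100]), 0.02)
    assert closed_form_drainage(0.01, 0.02, [100.0])[0] == pytest.approx(
        7.357589e-3, rel=1e-6
    )


def test_constant_rbar_simulation_matches_exponential_oracle(geom, buffer_fluid, nc_membrane):
    """With the mean plug radius frozen and a chamber-only plug, the ODE is
    linear and must match dr0 exp(-k t) with the closed-form k."""
    opts = SolverOptions(plug="chamber", constant_r_bar=True)
    prof = simulate_drainage(
        geom, buffer_fluid, nc_membrane, SpinProtocol.constant(1000.0, 500.0),
        VOLUME, opts,
    )
    dr0 = VOLUME / geom.chamber_area
    plug0 = FluidPlug(geom.r_chamber_outer - dr0, geom.r_chamber_outer)
    k = theoretical_decay_constant(
        geom, buffer_fluid, nc_membrane, rpm_to_omega(1000.0), plug0.r_bar
    )
    oracle = closed_form_drainage(k, dr0, prof.times)
    assert np.max(np.abs(prof.delta_r - oracle)) / dr0 < 1e-6


def test_no_flow_below_entry_threshold(geom, buffer_fluid, pvdf_membrane, initial_plug):
    """A hydrophobic membrane whose entry pressure is never reached acts as a
    closed valve: the column height never moves."""
    threshold = entry_threshold_rpm(geom, buffer_fluid, pvdf_membrane, initial_plug)
    assert threshold > 4000.0
    prof = simulate_drainage(
        geom, buffer_fluid, pvdf_membrane,
        SpinProtocol.constant(4000.0, 60.0), VOLUME,
    )
    assert np.all(prof.delta_r == prof.delta_r[0])
    assert np.all(prof.q == 0.0)
    assert not prof.wetted.any()


def test_volume_conservation_and_monotone_height(geom, buffer_fluid, nc_membrane):
    prof = simulate_drainage(
        geom, buffer_fluid, nc_membrane, SpinProtocol.constant(1500.0, 2000.0), VOLUME,
    )
    remaining = prof.delta_r * geom.chamber_area
    assert np.allclose(prof.cumulative_volume + remaining, VOLUME, atol=1e-9 * VOLUME + 1e-18)
    assert np.all(np.diff(prof.delta_r) <= 1e-15)
    # fully drains at this speed
    assert prof.delta_r[-1] == pytest.approx(0.0, abs=1e-9)


def test_stepped_protocol_wetting_is_one_way(geom, buffer_fluid, nc_membrane, initial_plug):
    """Spin-up through the threshold wets the membrane; spin-down afterwards
    does not close it again (wetted flag is monotone)."""
    threshold = entry_threshold_rpm(geom, buffer_fluid, nc_membrane, initial_plug)
    protocol = SpinProtocol(
        steps=((30.0, 0.6 * threshold), (30.0, 2.0 * threshold), (30.0, 0.6 * threshold))
    )
    prof = simulate_drainage(geom, buffer_fluid, nc_membrane, protocol, VOLUME)
    wet = prof.wetted.astype(int)
    assert np.all(np.diff(wet) >= 0)
    assert wet[0] == 0 and wet[-1] == 1
    # still draining on the spin-down step because the membrane stays wet
    last = prof.times > 60.0
    assert prof.delta_r[last][0] > prof.delta_r[last][-1]
    assert np.all(np.diff(prof.delta_r) <= 1e-15)


def test_full_model_is_nearly_first_order(geom, buffer_fluid, nc_membrane):
    """Semilog fit over the first 90% of drainage attains R^2 >= 0.99."""
    from discflow import fit_semilog

    prof = simulate_drainage(
        geom, buffer_fluid, nc_membrane, SpinProtocol.constant(1000.0, 3000.0), VOLUME,
    )
    dr0 = prof.delta_r[0]
    sel = prof.delta_r >= 0.1 * dr0
    fit = fit_semilog(prof.times[sel], prof.delta_r[sel])
    assert fit.r_squared >= 0.99


def test_theoretical_decay_constant_value_and_monotonicity(geom, buffer_fluid, nc_membrane):
    w = rpm_to_omega(1000.0)
    # hand arithmetic: rho w^2 rbar / (A (R_ch + R_mem)) at rbar = 0.04
    k = theoretical_decay_constant(geom, buffer_fluid, nc_membrane, w, 0.04)
    assert k == pytest.approx(4.59e-3, rel=1e-3)
    assert theoretical_decay_constant(
        geom, buffer_fluid, nc_membrane, 2 * w, 0.04
    ) == pytest.approx(4 * k)
    from discflow import Membrane

    mem_hi = Membrane(
        name="hi", pore_radius=nc_membrane.pore_radius,
        permeability=2 * nc_membrane.permeability,
        entry_pressure=nc_membrane.entry_pressure,
        thickness=nc_membrane.thickness, wetted_area=nc_membrane.wetted_area,
    )
    assert theoretical_decay_constant(geom, buffer_fluid, mem_hi, w, 0.04) > k


def test_entry_threshold_rpm_closed_form(geom, buffer_fluid, nc_membrane, initial_plug):
    rpm = entry_threshold_rpm(geom, buffer_fluid, nc_membrane, initial_plug)
    p = hydraulic_pressure(buffer_fluid, initial_plug, rpm_to_omega(rpm))
    assert p == pytest.approx(nc_membrane.entry_pressure, rel=1e-9)
    # fuller chamber wets at lower speed
    fuller = FluidPlug(initial_plug.r_meniscus - 2e-3, initial_plug.r_bottom)
    assert entry_threshold_rpm(geom, buffer_fluid, nc_membrane, fuller) < rpm


def test_entry_threshold_zero_pressure_and_empty_plug(geom, buffer_fluid, nc_membrane):
    from discflow import Membrane

    free = Membrane(
        name="free", pore_radius=2e-7, permeability=1e-14, entry_pressure=0.0,
        thickness=1.5e-4, wetted_area=3.14e-6,
    )
    plug = FluidPlug(0.02, 0.028)
    assert entry_threshold_rpm(geom, buffer_fluid, free, plug) == 0.0
    with pytest.raises(ValueError, match="empty plug"):
        entry_threshold_rpm(geom, buffer_fluid, nc_membrane, FluidPlug(0.028, 0.028))


def test_profile_dense_enough_for_micron_interpolation(geom, buffer_fluid, nc_membrane):
    """Linear interpolation between output samples errs well under 1 um."""
    prof = simulate_drainage(
        geom, buffer_fluid, nc_membrane, SpinProtocol.constant(2000.0, 500.0), VOLUME,
    )
    fine = simulate_drainage(
        geom, buffer_fluid, nc_membrane, SpinProtocol.constant(2000.0, 500.0), VOLUME,
        SolverOptions(max_sample_dt=0.02),
    )
    interp = np.interp(fine.times, prof.times, prof.delta_r)
    assert np.max(np.abs(interp - fine.delta_r)) < 1e-6


def test_simulate_rejects_overfull_chamber(geom, buffer_fluid, nc_membrane):
    with pytest.raises(ValueError, match="capacity"):
        simulate_drainage(
            geom, buffer_fluid, nc_membrane, SpinProtocol.constant(1000.0, 10.0),
            1.0,  # 1 m^3
        )


def test_spin_protocol_validation_and_lookup():
    with pytest.raises(ValueError):
        SpinProtocol(steps=())
    with pytest.raises(ValueError):
        SpinProtocol(steps=((10.0, -5.0),))
    p = SpinProtocol(steps=((10.0, 500.0), (5.0, 1500.0)))
    assert p.total_duration == 15.0
    assert p.rpm_at(0.0) == 500.0
    assert p.rpm_at(12.0) == 1500.0
    assert p.rpm_at(99.0) == 1500.0
    s = SpinProtocol(times=(0.0, 10.0), rpms=(0.0, 1000.0), interpolate=True)
    assert s.rpm_at(5.0) == pytest.approx(500.0)
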