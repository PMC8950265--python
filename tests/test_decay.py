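"""Decay fitting: exact recovery, OLS oracle, estimator cross-checks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from discflow import (
    FitError,
    closed_form_drainage,
    fit_condition_means,
    fit_nonlinear,
    fit_semilog,
    fit_study,
    relative_permeability,
    summarize_fits,
)


def exact_decay(k=0.01, y0=0.02, n=10, t_max=300.0):
    t = np.linspace(0.0, t_max, n)
    return t, closed_form_drainage(k, y0, t)


def test_semilog_exact_on_noiseless_exponential():
    t, y = exact_decay()
    fit = fit_semilog(t, y)
    assert fit.k == pytest.approx(0.01, rel=1e-12)
    assert fit.y0 == pytest.approx(0.02, rel=1e-12)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
    assert fit.n_points == 10


def test_two_points_always_give_unit_r_squared():
    fit = fit_semilog([3.0, 17.0], [0.02, 0.011])
    assert fit.r_squared == pytest.approx(1.0, abs=1e-12)


def test_semilog_matches_normal_equations_oracle():
    """On noisy data the fitted slope must equal the closed-form OLS normal
    equations evaluated independently on the same rows."""
    rng = np.random.default_rng(1)
    t = np.sort(rng.uniform(0.0, 400.0, 25))
    y = 0.02 * np.exp(-0.008 * t) * np.exp(rng.normal(0, 0.05, 25))
    fit = fit_semilog(t, y)
    # independent oracle: normal equations on (t - t0, ln y)
    tt = t - t[0]
    ly = np.log(y)
    n = len(tt)
    sx, sy_, sxx, sxy = tt.sum(), ly.sum(), (tt * tt).sum(), (tt * ly).sum()
    slope = (n * sxy - sx * sy_) / (n * sxx - sx * sx)
    intercept = (sy_ - slope * sx) / n
    assert fit.k == pytest.approx(-slope, rel=1e-10)
    assert fit.y0 == pytest.approx(np.exp(intercept), rel=1e-10)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(k=st.floats(1e-4, 1.0), y0=st.floats(1e-3, 1e-1))
def test_semilog_and_nonlinear_agree_on_exact_exponential(k, y0):
    t = np.linspace(0.0, 3.0 / k, 12)
    y = closed_form_drainage(k, y0, t)
    sl = fit_semilog(t, y)
    nl = fit_nonlinear(t, y)
    assert nl.k == pytest.approx(sl.k, rel=1e-8)
    assert sl.k == pytest.approx(k, rel=1e-9)


def test_nonlinear_beats_semilog_in_linear_space_with_additive_noise():
    rng = np.random.default_rng(3)
    t = np.linspace(0.0, 500.0, 30)
    y = 0.02 * np.exp(-0.007 * t) + rng.normal(0, 5e-4, 30)
    y = np.abs(y) + 1e-6
    sl = fit_semilog(t, y)
    nl = fit_nonlinear(t, y)

    def ss(fit):
        return np.sum((y - fit.y0 * np.exp(-fit.k * t)) ** 2)

    assert ss(nl) <= ss(sl) + 1e-18


def test_r_squared_invariant_to_time_unit():
    t, y = exact_decay()
    rng = np.random.default_rng(4)
    y = y * np.exp(rng.normal(0, 0.03, y.size))
    sec = fit_semilog(t, y)
    minutes = fit_semilog(t / 60.0, y)
    assert minutes.k == pytest.approx(60.0 * sec.k, rel=1e-10)
    assert minutes.r_squared == pytest.approx(sec.r_squared, abs=1e-12)


def test_duplicate_timestamps_averaged_and_plateau_dropped():
    t = [0.0, 10.0, 50.0, 50.0, 100.0]
    y = [0.01, 0.01, 0.006, 0.008, 0.004]  # flat start, tie at t=50
    fit = fit_semilog(t, y)
    # plateau re-origin: first retained time becomes 0
    assert fit.time_offset == pytest.approx(10.0)
    assert fit.n_points == 3  # onset, averaged tie, last


def test_nonpositive_heights_excluded_with_warning():
    t = np.linspace(0, 100, 6)
    y = np.array([0.01, 0.008, 0.006, 0.0, 0.002, 0.001])
    with pytest.warns(UserWarning, match="non-positive"):
        fit = fit_semilog(t, y)
    assert fit.n_points == 5
    with pytest.raises(FitError):
        with pytest.warns(UserWarning):
            fit_semilog([0.0, 1.0], [0.01, -0.01])


def test_nonlinear_recovery_against_its_noiseless_limit(
    geom, buffer_fluid, nc_membrane
):
    """At default noise the nonlinear k stays within 2% of the nonlinear fit
    of the same replicate's noiseless crossings."""
    from discflow import (
        NoiseModel,
        SpinProtocol,
        generate_observations,
        simulate_drainage,
    )

    prof = simulate_drainage(
        geom, buffer_fluid, nc_membrane, SpinProtocol.constant(1000.0, 5000.0), 200e-9
    )
    clean = generate_observations(prof, 1e-3, NoiseModel(timing_sd=0.0, seed=0))
    k_ref = fit_nonlinear(clean["crossing_time_s"], clean["graduation_height_m"]).k
    noisy = generate_observations(prof, 1e-3, NoiseModel(timing_sd=0.05, seed=1))
    k_hat = fit_nonlinear(noisy["crossing_time_s"], noisy["graduation_height_m"]).k
    assert abs(k_hat - k_ref) / k_ref < 0.02


def test_fit_study_zero_noise_replicates_identical(geom, buffer_fluid, nc_membrane):
    from discflow import NoiseModel, StudyDesign, generate_study

    design = StudyDesign(
        membranes=(nc_membrane,), matrices=(buffer_fluid,), rpms=(1500.0,),
        replicates=3, sample_volume=200e-9, graduation_spacing=1e-3,
    )
    obs = generate_study(
        design, geom, NoiseModel(timing_sd=0.0, permeability_cv=0.0, seed=1)
    )
    fits = fit_study(obs.table)
    ks = fits["k_per_s"].to_numpy()
    assert np.allclose(ks, ks[0], rtol=1e-9)


def test_fit_study_flags_no_flow_groups(geom, buffer_fluid, pvdf_membrane):
    from discflow import NoiseModel, StudyDesign, generate_study

    design = StudyDesign(
        membranes=(pvdf_membrane,), matrices=(buffer_fluid,), rpms=(1000.0,),
        replicates=2, sample_volume=200e-9, graduation_spacing=1e-3,
    )
    obs = generate_study(design, geom, NoiseModel(seed=1))
    fits = fit_study(obs.table)
    assert fits["no_flow"].all()
    assert fits["k_per_s"].isna().all()


def test_relative_permeability_reference_is_unity(default_study_obs):
    fits = fit_study(default_study_obs.table)
    est = relative_permeability(fits, "assay_buffer")
    assert est["assay_buffer"] == pytest.approx(1.0)
    with pytest.raises(ValueError, match="reference"):
        relative_permeability(fits, "not_a_matrix")


def test_condition_means_fit_uses_replicate_mean_times(small_study_obs):
    design, obs = small_study_obs
    mf = fit_condition_means(obs.table)
    assert len(mf) == len(design.rpms)
    # independent check for one condition
    grp = obs.table[obs.table["rpm"] == 1000.0]
    means = grp.groupby("graduation_height_m")["crossing_time_s"].mean().reset_index()
    ref = fit_semilog(means["crossing_time_s"], means["graduation_height_m"])
    row = mf[mf["rpm"] == 1000.0].iloc[0]
    assert row["k_per_s"] == pytest.approx(ref.k, rel=1e-12)
    assert row["r_squared"] == pytest.approx(ref.r_squared, abs=1e-12)


def test_summary_contains_group_means_and_sds(default_study_obs):
    fits = fit_study(default_study_obs.table)
    summary = summarize_fits(fits)
    assert set(summary.columns) >= {"membrane", "matrix", "rpm", "mean_k_per_s", "sd_k_per_s", "n"}
    assert (summary["n"] == 4).all()
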