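# Methods

## Model and assumptions

One testing domain of a centrifugal orthogonal-flow disc is modelled as a
lumped hydraulic network: a sample chamber of constant cross-section
`A_chamber` whose fluid column ends at radius `r_chamber_outer`, a connecting
channel treated as a Hagen–Poiseuille resistance
`R_ch = 32 η L / (D_h² A_ch)`, and a porous membrane across the OF port
treated as a Darcy resistance `R_mem = η t_mem / (κ_eff A_wet)` with
`κ_eff = κ · matrix_factor`. Flow crosses the membrane's thin axis, so the
Darcy path length is the membrane *thickness* and the Darcy area is the OF
port (wetted) area, not the membrane sheet dimensions.

Assumptions, in decreasing order of consequence:

- **Quasi-steady laminar flow.** Inertia and the Coriolis/Euler terms are
  neglected; only the centrifugal head `Δp_ω = ρ r̄ Δr ω²` drives flow.
  Valid for the mm-scale geometries and sub-µL/s discharges modelled here.
- **Lumped membrane.** The membrane is a single resistance plus a scalar
  entry pressure; no pore-network structure, saturation dynamics or
  recovery-chamber backpressure.
- **One-way wetting valve.** A dry membrane passes no flow until the head
  first reaches its entry pressure; once wetted it stays wetted even if the
  disc spins down. Capillary imbibition into the dry membrane is available
  separately as the Lucas–Washburn penetration length
  `l(t) = √(γ r cosθ t / 2η)` but does not feed back into the drainage ODE.
- **Primed channel (default plug).** The pressure-generating plug spans the
  meniscus to the membrane (`plug="full"`), i.e. the channel is full while
  flow persists. The literal chamber-only plug (`plug="chamber"`) is provided
  as an option; combined with `constant_r_bar=True` it makes the
  constant-speed solution exactly exponential, which is used as the solver
  oracle.
- **Matrix effects act on permeability only.** The three sample matrices are
  water-like in density and viscosity; composition enters solely as the
  permeability multiplier (urine 1.3, buffer 1.0, plasma 0.6 by default),
  modelling osmotic de-swelling/swelling of the cellulosic fibre network.

Under the full moving-meniscus model the drainage curve is only
*approximately* first-order: the primed channel contributes a head offset
`½ρω²(r_membrane² − r_chamber_outer²)` that does not vanish as the chamber
empties. For the reference geometry this keeps semilog fits over the
graduated range at R² ≈ 0.995 — strongly linear, but the fitted k is not
the frozen-r̄ `theoretical_decay_constant` (they differ by ~30% for the
reference device; the two agree only in the frozen-r̄, chamber-plug limit).

## Reference device parameters

No single published device fully specifies this geometry, so the packaged
defaults are one self-consistent, realistic parameterisation of a Ø 70 mm
disc domain; all are plain config values, not constants.

| parameter | default | why |
|---|---|---|
| chamber area | 20 mm² | 200 µL → 10 mm column, matching ten 1 mm graduations |
| r_chamber_outer | 28 mm | chamber placed close to the membrane (the regime of interest) |
| r_membrane | 28.5 mm | OF port just beyond the chamber bottom |
| channel D_h, L, area | 0.5 mm, 10 mm, 1 mm² | typical milled/laminated channel; R_ch = 1.28e9 Pa·s/m³ |
| NC 0.2 µm: κ, p_entry | 1e-14 m², 500 Pa | R_mem = 4.78e12 Pa·s/m³ ≫ R_ch (membrane-limited flow); wets near 400 rpm, consistent with cellulosic membranes flowing slightly above 500 rpm |
| NC 0.45 µm: κ, p_entry | 2.5e-14 m², 300 Pa | larger-pore membrane drains ~2.5× faster |
| PVDF: p_entry, θ | 60 kPa, 2.1 rad | hydrophobic; no flow anywhere below ~4500 rpm, the valving regime |
| g | 9.81 m/s² | standard gravity for ×g conversion |
| max rpm (protocol designer) | 6000 | bench spin controllers sweep to ~5500 rpm |

Decay constants that follow: k ≈ 1.9e-3 /s at 750 rpm rising to
1.5e-2 /s at 2000 rpm for buffer through the 0.2 µm membrane, i.e. drain
times of minutes down to ~100 s for 200 µL — bench-realistic magnitudes.

## Synthetic observation model

The generator emulates graduation-timed videography of the receding
meniscus. Per replicate it (1) draws a membrane permeability from a
lognormal with unit mean and CV `permeability_cv` (default 0.10) —
replicate-to-replicate variability is attributed to the non-uniform 3D pore
network of individual membrane cutouts, not to geometry; (2) applies the
fluid's matrix factor; (3) integrates the drainage ODE at constant speed
until the chamber empties; (4) linearly interpolates the crossing time of
each 1 mm graduation below the initial column; and (5) adds Gaussian timing
jitter (`timing_sd`, default 0.05 s, the scale of frame-timing uncertainty)
and re-sorts to preserve the physically required monotonicity. All draws
come from one explicitly seeded generator; the full study table is
deterministic given the seed.

A sidecar records, per replicate, the drawn permeability, the effective
permeability, and the **true decay constant**, defined as the semilog fit to
that replicate's *noiseless* crossings. This definition was chosen because
the full model is not exactly exponential: the decay constant that
"generated" the observations is a property of the noiseless curve, not the
frozen-r̄ formula. Parameter-recovery tests for the semilog estimator use
this truth (median relative error ~5e-5 at default noise). The nonlinear
estimator weights the slight model misfit differently and sits ~8% below the
semilog value on the *same noiseless data*; its recovery is therefore judged
against the nonlinear fit of the noiseless crossings, isolating noise
sensitivity from model misfit.

What the emulation does **not** contain, and hence what passing tests do not
show about real data: membrane fouling or saturation drift over a run,
meniscus curvature and optical read-out error structure, temperature and
evaporation effects, non-Gaussian timing outliers, and any within-replicate
permeability change. Recovery results bound estimator error under the stated
noise model only.

## Fitting

The primary estimator is ordinary least squares of ln(Δr) on elapsed time
(`fit_semilog`): k = −slope, y₀ = exp(intercept), R² computed in ln space —
the space in which the linearized decay is reported. Nonlinear least squares
in linear space (`fit_nonlinear`, initialized from the semilog fit) is the
cross-check. Cleaning rules: non-positive heights are excluded (with a
warning), duplicate timestamps are averaged, any pre-wetting plateau is
dropped and time is re-origined to drainage onset (the decay law describes
the draining phase only). Condition-level "means-based" fits regress
ln(height) on the replicate-mean elapsed time at each graduation — the
primary reported quantity — alongside per-replicate fits.

`relative_permeability` estimates per-matrix factors as the ratio of mean
fitted k to the reference matrix's mean k at the same (membrane, speed),
averaged over conditions. This identifies the matrix factor because k is
linear in κ_eff whenever the membrane dominates the series resistance (here
R_mem/R_ch ≈ 3.7e3, so the approximation error is negligible).

## Protocol design

Holding the head at Δp\* makes the discharge Q = Δp\*/(R_ch+R_mem) constant,
so the meniscus moves linearly in time and the required speed
ω(t) = √(2Δp\*/(ρ(r_membrane² − r_men(t)²))) has a closed form; no iteration
is needed. Continuous output is a 400-sample linearly interpolated schedule;
stepped output holds each step at the speed correct for the step-midpoint
plug state, bounding within-step pressure error (simulated discharge CV
≈ 0.003% continuous, ≈ 1.2% at 5 s steps for the reference device). The
schedule is monotone increasing and is truncated, with a flag, where it
would exceed the speed cap. The designed schedule is close to exponential in
time but is reported as computed rather than forced to exponential form.

## Numerical choices

- ODE: `scipy.integrate.solve_ivp` (RK45), rtol 1e-8, atol 1e-12 m, with a
  terminal event at chamber-empty; integration restarts at protocol-step
  boundaries since ω jumps there. Output sampling at ≤ 0.25 s spacing
  (capped at 20001 samples/segment) keeps linear interpolation of Δr(t)
  below 1 µm error for fixture-scale devices.
- Wetting detection: under piecewise-constant protocols a dry membrane's
  head only changes at step boundaries (no flow → frozen state), so wetting
  is checked at segment starts; sampled time-varying schedules are scanned
  on a 2048-interval grid for the first wetting instant.
- Semilog OLS via `numpy.linalg.lstsq`; nonlinear via
  `scipy.optimize.curve_fit` with the semilog start.
- Time re-origin keeps exp(intercept) interpretable as the height at
  drainage onset.
- Degenerate inputs: empty plug with positive entry pressure raises
  (infinite threshold); graduation spacing wider than the column warns and
  returns an empty table; no-flow conditions are flagged rather than
  dropped.

## Study sizes used in tests and the acceptance script

The default study is 2 membranes × 3 matrices × 6 speeds × 4 replicates
(144 simulated trials, ~2 s); the recovery harness uses 100 replicates of
one condition. These sizes give the study the same shape as a bench
characterisation campaign while keeping the whole suite fast enough to run
on every change.

## Known limitations

- The lumped, quasi-steady model cannot represent partial membrane
  saturation, bypass leakage, or air counterflow in the recovery chamber.
- Entry pressure is a single scalar; real wetting is gradual and
  history-dependent.
- The matrix factor is a one-parameter stand-in for solute–polymer
  thermodynamics; it reproduces ordering and magnitude of throughput
  differences, not their chemistry.
- Motor ramps are not modelled: stepped protocols change speed
  instantaneously.
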