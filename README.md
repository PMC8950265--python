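# discflow

Drainage modelling for **centrifugal orthogonal-flow (cOF) microfluidic
discs** — lab-on-a-disc devices in which a spinning disc pumps a liquid
sample out of a chamber, through a channel, and *orthogonally* through a
nanoporous membrane embedded in the disc. These devices underpin
point-of-care immunoassays that need pressure-driven (rather than purely
capillary) flow through a capture membrane.

`discflow` is for device designers and assay developers who need to predict
and analyse drainage behaviour: how fast a sample chamber empties at a given
spin speed, when a dry membrane first wets, how sample-matrix composition
changes throughput, and what spin schedule keeps the flow rate constant as
the chamber drains.

## Model

A fluid plug spanning radial positions *r_men* (meniscus) to *r_bot* on a
disc spinning at angular frequency ω experiences the centrifugal pressure
head

    Δp_ω = ρ r̄ Δr ω² = ½ ρ ω² (r_bot² − r_men²),

with r̄ the mean plug radius and Δr its radial extent. The head drives flow
through the series hydraulic resistance of the connecting channel
(Hagen–Poiseuille, `R_ch = 32 η L / (D_h² A_ch)`) and the membrane (Darcy,
`R_mem = η t_mem / (κ_eff A_wet)`), where `κ_eff = κ · matrix_factor`
lumps the effect of sample-matrix composition (osmotic swelling or
de-swelling of cellulosic fibres) into a scalar permeability multiplier.
A dry membrane passes no flow until Δp_ω first exceeds its **entry
pressure**; wetting is a one-way valve event. Drainage obeys

    A_chamber · d(Δr)/dt = −Δp_ω / (R_ch + R_mem),

so as the column falls the head falls with it and the column height decays
approximately as a first-order process, Δr(t) ≈ Δr₀ e^(−kt), with

    k = ρ ω² r̄ / (A_chamber (R_ch + R_mem))

in the frozen-r̄ limit. The package integrates the full moving-meniscus ODE
under arbitrary spin protocols, emulates graduation-timed videography
observations of the receding meniscus, extracts k and R² by semilog or
nonlinear least squares, and designs compensating spin protocols
ω(t) = √(Δp\*/(ρ r̄(t) Δr(t))) that hold the head — hence the discharge —
constant while the chamber empties.

## Worked example

Run the default emulated drainage study (two nitrocellulose membranes ×
three sample matrices × 750–2000 rpm in 250 rpm steps, n = 4 replicates of
200 µL read against 1 mm graduations) and summarise the fitted decay
constants:

```python
import discflow as df

cfg = df.default_config(seed=1)
obs = df.generate_study(cfg.study, cfg.geometry, cfg.noise)
fits = df.fit_study(obs.table)
print(df.summarize_fits(fits).query("membrane=='nc_0.2um' and matrix=='assay_buffer'"))
print(df.relative_permeability(fits, "assay_buffer"))
```

which prints

```
membrane       matrix    rpm  mean_k_per_s  sd_k_per_s  n
nc_0.2um assay_buffer  750.0      0.001901    0.000079  4
nc_0.2um assay_buffer 1000.0      0.003454    0.000269  4
nc_0.2um assay_buffer 1250.0      0.005520    0.000506  4
nc_0.2um assay_buffer 1500.0      0.008702    0.000765  4
nc_0.2um assay_buffer 1750.0      0.010297    0.001705  4
nc_0.2um assay_buffer 2000.0      0.015084    0.001454  4

artificial_plasma    0.595195
artificial_urine     1.314607
assay_buffer         1.000000
```

The decay constant k (1/s) is the rate at which the fluid column recedes:
it grows quadratically with spin speed (doubling the speed roughly
quadruples k) and linearly with effective membrane permeability. The second
block is the per-matrix permeability multiplier estimated from ratios of
fitted k values against the assay-buffer reference — it recovers the
generating factors (urine 1.3, buffer 1.0, plasma 0.6), reproducing the
characteristic throughput ordering artificial urine > assay buffer >
artificial plasma.

The same pipeline is scriptable from the shell:

```sh
discflow run-study --seed 1 --out-dir results/
discflow rcf 500 50                 # relative centrifugal force at 500 rpm, 50 mm
discflow design-protocol --target 2000 --out protocol.json
```

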