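# Methods

`prepsim` models an automated NGS library-preparation platform in which
all liquid handling happens in a 384 deep-well plate through two cannula
tips, and all heated reactions happen inside pressurised cylindrical
fluid slugs in capillary tubing clamped to a Peltier-heated copper
plate. The package has three quantitative cores — a deterministic
efficiency cascade, a fragment-level stochastic simulator consistent
with it, and a lumped thermal model — plus protocol definitions, QC
metrics and synthetic-data generators that make every part testable
without external data.

## The efficiency cascade

The cascade converts an input DNA mass m_in into a theoretical final
library concentration through the stage efficiencies of the assay:

    N_DNA = m_in N_A / (650 ⟨l_bpi⟩)
    N_AL  = η_lig N_DNA
    N_PCR = 2^n η_wash η_AL η_PCR N_AL
    N_out = N_PCR η_wash (1 − F_ads)(1 − F_LT)
    m_out = 650 (N_out/N_A) ⟨l_bpi⟩² / (⟨l_bpi⟩ + 2 l_A)
    C_f   = m_out / V_RsB

with N_A Avogadro's number, 650 g/mol per base pair, ⟨l_bpi⟩ the mean
insert length, l_A the single-adapter length, n the PCR cycle count,
and V_RsB the final resuspension volume. η_wash is the composite SPRI
wash efficiency (bead binding × elution × bead retention) and appears
twice because the post-ligation and post-PCR purifications follow the
same protocol; C_f is therefore proportional to η_wash². F_ads and
F_LT are the fractions lost to tubing adsorption and liquid transfers.

Built-in parameter sets (`table_params`): mechanical assay — 20 ng
input at 260 bp, η_lig 0.60, η_wash 0.73, η_PCR 0.95, n = 8, F_ads
0.05, F_LT 0.15, l_A 70 bp, V_RsB 33 µL (C_f ≈ 24.7 ng/µL); enzymatic
assay — 50 ng at 250 bp, η_lig 0.65, η_wash 0.77, l_A 75 bp, V_RsB
22 µL (C_f ≈ 107.5 ng/µL).

Two deliberate conventions:

* **η_AL** is an extra post-ligation survival factor in the PCR step.
  No established value exists for it separately from η_wash, so it
  defaults to 1 (which reproduces the reference table) and is exposed
  as an ordinary parameter.
* **Mass conversion.** The default (`"as_printed"`) m_out formula above
  scales as l²/(l+2l_A); it is the published model form and the one the
  reference table's 809/2360 ng outputs follow. It differs from the
  molar mass of the full adapter-ligated molecule, which the
  `"physical"` mode provides (650 (N_out/N_A)(l+2l_A), ≈ 1930 ng for
  the mechanical column). Both are implemented; no intent is guessed
  and the default is the table-reproducing form.

`invert_for_efficiency` solves C_f for any single unknown efficiency by
bracketing root-finding (Brent) on [0, 1] to 1e-6 absolute tolerance;
C_f is strictly monotone in each single efficiency so the root is
unique. Observations outside the attainable range return the boundary,
flagged.

## The stochastic simulator

`simulate_assay` tracks integer molecule counts per (length bp, species)
class through fragmentation → ligation → SPRI wash → PCR → SPRI wash →
losses. Species are `insert`, `adapter_ligated_insert` and
`adapter_dimer`. Every stage randomisation has an expectation equal to
the corresponding cascade factor:

* **Fragmentation / input.** Insert lengths are lognormal with the
  assay's mean insert size and CV 0.30 by default (only mean input
  lengths are specified for the real assays; 0.30 gives
  electropherogram-like 200–1000 bp spreads and is user-overridable).
  The mechanical assay's input arrives pre-sheared; operationally both
  assays start by drawing this population.
* **Ligation.** Binomial thinning at η_lig; ligated inserts gain 2 l_A
  bp. Adapter-dimers form Poisson(dimer_rate × inputs) at length 2 l_A.
  The default dimer_rate of 1.0 expected dimer per input molecule is a
  tunable calibrated so the *final* dimer mass fraction lands in the
  0.1–0.5% range typical of passing libraries (~0.13% with defaults);
  most dimers are removed by the washes.
* **SPRI washes.** Retention is logistic in length
  (η_max/(1+exp(−(l−l50)/s)), defaults l50 = 200 bp, s = 20 bp —
  the post-PCR cleanup's <200 bp removal target). Before each wash
  the curve's η_max is solved (exactly, the mean is linear in η_max) so
  the count-weighted mean retention of adapter-ligated molecules equals
  η_wash for the *current* population; both washes therefore achieve
  the same composite efficiency, as the two purifications follow the
  same protocol. Dimers at ~140–150 bp sit low on the curve and are
  preferentially removed.
* **PCR.** Adapter-ligated inserts and adapter-dimers amplify (both
  carry primer sites); bare inserts pass through. Default `"paper"`
  mode draws Binomial(count·2^n, η_PCR) per class; `"per_cycle"` mode
  runs n Galton–Watson doubling cycles at duplication probability
  p_c = (2^n η_PCR)^{1/n} − 1. Both have mean 2^n η_PCR; per-cycle mode
  adds realistic cycle-to-cycle dispersion.
* **Losses.** Binomial thinning at (1−F_ads)(1−F_LT).

**Desk scale.** 1e5 founder molecules stand in for the ~1e10–1e11 real
input molecules; all stage expectations are linear in count, so counts
and masses scale exactly by the founder-to-real ratio, which the result
carries. One run takes ~10 ms; the 200-replicate mean-field checks run
in about a second per assay.

**Yield convention.** The reported m_out/C_f convert the final
adapter-ligated molecule count with the cascade's mass formula at the
nominal insert length. This is deliberate: the logistic wash retains
longer survivors preferentially, so summing per-length masses would
exceed η_wash × (input mass) by a systematic few percent and the
simulator's mean concentration would no longer estimate the cascade's —
the two models would answer subtly different questions. With the count
convention, the replicate mean of every stage count and of C_f equals
the cascade value exactly in expectation (verified to 3 standard errors
at 200 replicates). The per-length physical masses remain fully
available on `final_population`, and drive the electropherogram
histogram and the adapter-dimer mass percentage. m_out counts
sequence-able molecules only: dimers are reported separately as
`percent_adapter_dimer`, and unligated inserts are excluded.

**Randomness.** One root seed; each pipeline stage draws from its own
child stream spawned from `numpy.random.SeedSequence(seed)` in fixed
order, so results are bit-reproducible and a change in one stage's
draw count does not perturb the others.

Degenerate inputs: η_lig = 0 leaves no molecules to calibrate the wash
against; the wash then falls back to an uncalibrated curve capped at
η_wash and the run completes with zero library mass.

## The thermal model

Closed-form estimates (SI units): cylindrical-shell conduction
Q = 2πkrL(ΔT/Δr); with the slug parameters (k = 0.598 W/m·°C,
r = Δr = 0.8 mm, L = 24.9 mm, ΔT = 73 °C) Q ≈ 6.8 W, and with the wall
parameters (k = 0.33, r = 1.6 mm) ≈ 7.5 W — matched within ~10%, which
is the design point: wall and slug conduct comparably so the slug
tracks the block. Radial diffusion time t_d = r²/2α ≈ 2.1 s, and the
slug's capacitance-to-conduction timescale ≈ 0.54 s, so the liquid
equilibrates in seconds. Well-mixing scales: diffusional τ_d = w²/2D
and convective τ_c = w²L/Q_flow for the 3.48 × 3.48 × 19.3 mm wells.

The trace simulator integrates a lumped first-order plant
C_th dT/dt = u − h(T − T_amb) by explicit Euler (default dt 0.1 s, with
a stability guard), under PID control of the heater with output clipped
to [0, u_max] (heat-only; a bidirectional mode models Peltier cooling)
and integral anti-windup. Each scripted setpoint segment is tracked
until the temperature is within 1 °C, then held for its scripted time —
as a thermal cycler sequences ramps and holds — so total duration is
scripted holds plus realised ramps. Gaussian sensor noise (default SD
0.1 °C, seeded) is added to the measured channel and fed back to the
controller.

Plant and controller constants are not measured quantities; the
defaults (C_th 13 J/°C, h 0.10 W/°C, u_max 40 W, K_p 20 W/°C,
K_i 0.5 W/(°C·s)) were chosen from the physics so that the 20→98 °C
rise completes in under 30 s and the simulated 8-cycle PCR program
(hold total exactly 750 s) takes ≈ 23.6 min, inside the ~22–25 min
bracket of real cyclers. All are configuration-exposed.
`trace_metrics` scores each segment for ramp rate (10→90% rise),
settling time to ±1 °C (reported absent if never reached), steady-state
error (mean over the final quarter) and direction-aware overshoot.
Thermal logs are plain tab-separated text
(`time_s  setpoint_C  measured_C`), round-tripping to 1e-3 °C.

## QC metrics

`assess_library` applies the standard passing criteria — total yield
≥ 250 ng, concentration ≥ 5 ng/µL (the minimum sequence-able input),
adapter-dimer ≤ 5% by mass, and ≥ 80% of mass inside the 200–1000 bp
window — with inclusive comparisons at the boundaries and all
thresholds overridable. `measure_concentration` models fluorometric
quantification as multiplicative Gaussian noise with CV 0.12 (the
instrument's stated ±12% error read as a symmetric CV), truncated at
zero. Replicate summaries use the sample (n−1) standard deviation.

`normalized_coverage_by_gc` is a toy, single-strand GC-bias metric:
each read contributes the integer GC percent of the 100 bp reference
window anchored at its start (0-based, half-open); reads outside the
20–60% GC range are excluded; per-bin counts are divided by the mean
over occupied bins, so the profile averages exactly 1. Read-anchored
(rather than tiled) windows were chosen as the simplest convention
consistent with a fixed "window-size"; reverse-strand handling and real
alignment are out of scope.

## Synthetic data

Generators are pure functions of their spec and seed.
`generate_replicate_concentrations` emulates one plate (default eight
parallel lanes): a stochastic assay run per replicate plus one noisy
measurement. `recover_efficiency` closes the loop by inverting the
cascade at the dataset mean, with a nonparametric bootstrap percentile
interval (default 1000 resamples); with truth η_wash = 0.73, eight
replicates and 12% measurement CV, the recovery error is ~0.01–0.02 and
shrinks ∝ 1/√n (checked over n ∈ {8, 32, 128}). `generate_gc_fixture`
builds references from exact-GC 100 bp blocks with block-anchored reads
drawn at per-bin relative rates, and `generate_thermal_fixture` writes
seeded thermal logs.

## What the synthetic conditions do and do not show

The generators reproduce the *structure* of the real experiments —
sample sizes, stated noise levels, stage efficiencies, size-selection
behaviour — not the biology: there are no sequences, no enzyme
kinetics, no bead physics, and the measured plate-to-plate variance
components of a real instrument are larger than simulation variance
plus measurement CV. Passing tests therefore demonstrate internal
consistency of the models and correct implementation of the published
formulas, not predictions about a particular instrument run. Real
per-sample plate data and sequencing reads are outside the package's
scope by design.

## Known limitations

* The cascade is a mean model; it carries no variance and its printed
  intermediates are reproduced to 2% (the reference table rounds).
* The as-printed mass formula is dimensionally a mass but is not the
  adapter-ligated molar mass; both conventions are provided (above).
* The thermal plant is zero-dimensional; no conduction PDE, no
  evaporation model, no Peltier device physics.
* The dimer-formation rate is a tunable with a plausible default, not
  an estimated chemical constant.
* SPRI selectivity is a two-parameter logistic; real bead chemistry
  depends on buffer ratio and bead lot.
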