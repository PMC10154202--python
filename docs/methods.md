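# Methods

This note records the models implemented in `macroqs`, their
assumptions, the parameter conventions, and the design choices made
where the design was genuinely open.

## Deterministic growth laws

All three phenomenological laws integrate
dN/dt = (1 − N/K_cap)·r(N)·N with N a *continuous* population size — no
rounding to integers, since these are continuum models. Time is in hours
throughout the package (trajectories are reported on a 1-h grid by
default, mirroring the stochastic model's timestep).

* autonomous: r(N) = r (constant);
* collective: r(N) = μ_max·N/(K_M + N) + r₀, with r₀ > 0 (no threshold)
  or r₀ ≤ 0 with μ_max + r₀ > 0 (Allee threshold at
  N\* = K_M(−r₀)/(μ_max + r₀)).

The threshold is computed in closed form and cross-checked in the tests
by bracketed root finding (relative tolerance 1e-9). Integration uses
scipy's adaptive LSODA with rtol = atol = 1e-9; integration failure
raises rather than returning NaNs, and the autonomous integrator is
validated against the analytic logistic solution to 1e-6 relative.

A note on fold-change ordering: fold change at fixed t₁ is bounded above
by K_cap/N₀, so it *cannot* be monotone in N₀ all the way to the
carrying capacity for any law. The ordering that distinguishes the three
laws — larger populations fare better under collective growth, and only
the with-threshold law produces fold changes below 1 — holds for
N₀ ≪ K_cap, and that is the regime the tests assert.

## Stochastic quorum model

State: integer cell count N_t and factor concentration M_t, measured in
units of the per-cell secretion rate (secretion is 1/V per cell per
step, V in ml); no mapping to physical concentration units is attempted.
Per 1-h step:

* M_{t+1} = N_t/V + d·M_t with the *pre-update* count N_t; M₀ = 0;
* births R_t and deaths D_t are **independent** binomial draws on the
  same N_t (no joint constraint), with P_μ = μ·M_t/(K + M_t) and P_γ = γ;
  probabilities are per-step, not rates. N is clamped at zero in the
  extreme event D_t − R_t > N_t.

Defaults are the measured values μ = 0.052, γ = 0.023, d = 0.99,
K = 4.85×10⁵, V = 10 ml. The growth area only converts counts to
densities and defaults to 78.54 cm² (nominal 10-cm dish); the time-lapse
condition helper uses a 6-cm dish (28.27 cm²) with 4 ml. There is no
carrying capacity in this model: "expanded" is defined by fold change.

Outcome classification: a trajectory is *extinct* if its fold change at
day 6 is below 0.6, *expanded* if its fold change at the horizon exceeds
1 and the trailing 24-h trend is nonnegative, else *undecided*. The
threshold density is defined as the 50% crossing of the extinction
fraction, located by bisection on the initial density with a fixed
replicate count per level (default 10) and ~2% relative resolution; the
50% convention is a declared choice (the experimental threshold is
qualitative). Both the 6-day and 16-day horizons are exposed; 6 days is
the default because the phase-diagram classification uses it.

Randomness: one root seed per ensemble, split into per-replicate child
streams with `numpy.random.SeedSequence.spawn`, so ensembles are
reproducible bit-for-bit and replicates are independent. Counts are
int64 and safe beyond 1e9 cells.

Phase diagram: 8 replicates per (V, density) condition by default;
conditions are labeled always-extinct/always-survives/both-possible, and
the boundary is the per-volume bisected threshold. Because M scales as
N/V, the boundary rises roughly linearly with V.

## Communication range (reaction–diffusion)

The point-source profile (R/r)·e^{−(r−R)/λ} is the steady state of the
spherically symmetric reaction–diffusion equation with first-order
degradation; the tests verify this against a numerical boundary-value
solution. The concentric-ring colony sum places N_m ≈ 2mπ cells (a
continuous approximation, not rounded) at distance r_m = (2m−1)R from
the receiver cell's surface; the receiver never contributes to its own
c_tot. Infinite sums are truncated when the geometric tail bound falls
below 1e-12 of the accumulated value. The saturation radius is the
smallest colony radius whose missing tail of c_tot is below a relative
tolerance (default 5%); it is of order λ, and diverges (returns `inf`)
when λ is infinite.

Stokes–Einstein: the hydrodynamic radius is that of a sphere of density
1.35 g/cm³ (typical globular protein) with the molecule's mass; defaults
T = 310 K and η = 6.9×10⁻⁴ Pa·s (water at 37 °C) are declared package
constants, not inferred values. The lifetime τ in λ = √(Dτ) is the
half-life *verbatim*; a `use_mean_lifetime` switch substitutes
t½/ln 2 for users who prefer the mean-lifetime convention. For a 22-kDa
molecule with τ = 72 h this gives D ≈ 1.8×10⁻¹⁰ m²/s and λ ≈ 6.8 mm.

The half-space geometry of cells adhered to a dish bottom is absorbed
into the surface concentration c_R: all colony results are expressed in
units of c_R, so the full-space/half-space factor cancels.

## Rate estimation

The dead-area record is ambiguous as a direct exponential target — a
cumulative series is nondecreasing — so two interpretations are
implemented and named:

* **survival mode (default):** per-frame hazard h_t = ΔC_t/A_{t−1}
  (dead-area increment over alive area), cohort survival
  S_t = Π(1 − h_s), fitted log-linearly as e^{−γt}. This is exact for
  the generating model at any density, growing or shrinking.
* **literal mode:** fit C(t) = C_∞(1 − e^{−γt}) to the cumulative series
  directly. This recovers γ exactly for a pure-death population but is
  biased when births are appreciable (the dead-area increments then
  track N_t, not e^{−γt}); it is provided as the literal reading, not
  recommended for growing dishes.

Per-density rates are averaged; the pooled stderr is the cross-density
scatter (sd/√n) floored at the typical per-fit stderr. A heterogeneity
flag fires only when a density's rate deviates from the pooled median by
more than 3× the robust dispersion *and* by more than 10% of the rate —
regression stderrs on smooth cumulative curves understate replicate
noise, so a pure significance test would flag trivial Monte-Carlo
scatter.

Growth: μ_net per density is a log-linear fit to total alive area;
μ = max(μ_net) + γ. Because the model starts at M₀ = 0, the net rate
only approaches its ceiling μ − γ once M ≫ K, which takes ~2 days at
high density; the declared default window for recovery-style growth fits
is therefore t = 48–96 h (`SATURATED_GROWTH_WINDOW`), and recovery
designs include seeding densities up to 15,517 cells/cm² (the top of the
studied range, `RECOVERY_DENSITIES`) where saturation is reached inside
the window. With only the eight imaged densities (455–4,091 cells/cm²)
and a full-window fit, μ is structurally underestimated (~0.037–0.040
for a true 0.052) — a property of the model's factor-accumulation lag,
not a fitting defect. All estimates are invariant to the assumed mean
cell area (tested), since only area ratios enter.

## Synthetic data generator

The generator emulates the sparse-seeding observational design: uniform
random colony positions on a disk-shaped dish, 1–3 cells per colony
(declared default; initial areas are near-identical across densities),
80 µm² mean cell area (10-µm footprint; only used for area↔count
conversion), hourly frames over 96 h, fields of view of
1,399.16 × 994.95 µm. All colonies on a dish share one concentration M_t
(well-mixed: the diffusion length far exceeds colony spacing); per-colony
counts evolve by the binomial rules; every cell death detaches one mean
cell area into the cumulative dead-area record, and a colony reaching
zero cells is marked detached. Ground truth is emitted alongside every
dataset, and all CSV writers/readers round-trip bit-exactly
(`%.17g` formatting, round-trip float parsing).

What the generator does **not** emulate, hence what passing tests do not
show about real data:

* whole-colony lift-off: real microcolonies often die and detach as a
  unit; the generator detaches cell-by-cell. Correlation analyses are
  therefore performed on still-attached (observable) colonies, matching
  what a microscope can measure.
* short-range exclusion or aggregation at seeding: positions are exactly
  Poisson, so the mean nearest-neighbor spacing follows 1/(2√ρ). At the
  most extreme density studied (~15,000 cells/cm²) this drops below the
  ~100 µm floor reported for real dishes; the spacing checks are
  asserted at the canonical high density (5,172 cells/cm², Poisson mean
  ≈ 98 µm).
* progenitor/differentiated subpopulations, time-varying rates,
  multiple independently secreted factors, spatial concentration
  gradients, and image segmentation noise are all out of scope.

## Problem sizes

Default test and example runs use 10–100 replicate populations per
condition, dishes of up to ~2×10⁵ colonies, 96–384-h horizons, and
8-volume × 8-density phase grids; the full suite and all examples
complete in well under a minute on one CPU, and all stochastic results
are reproducible from the printed seeds.
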