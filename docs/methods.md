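# Methods

This note records the models implemented in `bilayermech`, the choices made
where the physics or the numerics were genuinely open, and what the
synthetic-data tests do and do not demonstrate.

## Pendant-drop tensiometry

A pendant drop of density contrast Δρ hanging in a lighter fluid satisfies
the Young–Laplace balance. With the apex at the origin and z increasing
toward the needle, the axisymmetric shape in arc-length form (lengths in
units of the apex radius b) is

    dx/ds = cos φ,  dz/ds = sin φ,  dφ/ds = 2 − Bo·z − sin φ / x,

with Bond number Bo = Δρ g b²/γ (= Δρ g b² ·10⁻³/γ in the package units
mm, mN/m, kg/m³). The arc-length form avoids the turning-point
singularities of z(x) parametrisations; the apex singularity of sin φ/x is
handled by starting one step off the apex with the spherical series
x ≈ s, z ≈ s²/2, φ ≈ s. Integration uses `scipy.integrate.solve_ivp`
(RK45, rtol 10⁻¹⁰ for profile generation, 10⁻⁸ inside the fitting loop
where polyline discretisation dominates the error budget). Integration
stops, with a truncation flag, where the contour closes onto the axis,
folds past φ = π, or the tangent angle returns through zero (a hanging
drop must have nondecreasing z).

**Inverse problem.** `PendantDropFitter` minimises the symmetric
point-to-polyline distance between the data and a model contour over
(γ, b, apex z-offset) with `least_squares`. The apex radius and offset are
initialised by an axis-constrained osculating-circle fit; candidate Bond
numbers (log-spaced in [0.05, 1.5]) are screened by a single objective
evaluation and the best two are refined. Identifiability requires Δρ ≠ 0:
a weightless drop is spherical at every tension, and the fitter raises an
error rather than returning an arbitrary γ. Default Δρ = 140 kg/m³
(water ≈ 1000 vs squalene ≈ 858 kg/m³), configurable.

**Plateau detection.** Tensiometer traces equilibrate as lipid adsorbs;
the measured value is the terminal plateau. The detector computes rolling
linear slopes over windows of 10 % of the trace span (configurable) and
reports the mean over the earliest terminal segment in which every window
stays below `slope_tol` (default 10⁻³ mN/m per s). A trace with no quiet
final window raises a no-plateau error rather than reporting a drifting
value.

## Young–Dupré bilayer tension

At the DiB three-phase contact line, Γ = 2γ cos θ with 2θ the full angle
between the droplet caps. Angles are degrees at the interface, radians
internally. Replicates (typically 20–30 angle measurements per condition)
are aggregated as mean ± standard error of the mean; the reference tables'
± entries are interpreted as s.e.m. on the same grounds (they are
described as averages of 20–30 measurements). The inverse map
`contact_angle_from_tensions` is exact on 0 ≤ Γ ≤ 2γ and is what the
synthetic angle generator uses.

## Elastic stretching model

The model free energy per unit projected cell area at coverage φ,

    f(u) = −2 k |ζ| φ u + (k/2) (φ u²)²,

is a reconstruction: the published integrand is not available in the
source text, so the energy was rebuilt from its verbal description and the
cell geometry. The choices, stated openly:

* per-particle unit cell of unperturbed area S₀ = πR²/φ; spherical-cap
  contact area 2πR²u with u = 1 − cos ψ;
* the suspended region is taken flat and taut, so the area drawn into the
  cap sets a global strain α = φu² (exact cap geometry πR²(1 − cos ψ)²/S₀);
* the adsorption gain is linearised in α (the n₀/(1+α) dilution of
  adsorption sites enters only through the stretching penalty);
* wrapping is capped at the hemisphere, u ≤ 1, where the flat-annulus
  geometry breaks down — particle engulfment is outside the model;
* the tension rise is the linear elastic law ΔΓ = k α\*, with the same k
  as in the energy.

Minimisation gives u\* = min(1, (|ζ|/φ)^⅓) and

    ΔΓ = k φ^⅓ |ζ|^⅔   for φ > |ζ|   (partial wrapping),
    ΔΓ = k φ           for φ ≤ |ζ|   (hemisphere cap),

continuous at φ = |ζ|. A property test checks the closed form against
brute-force minimisation of f(u) to 10⁻⁸ over random parameter draws.

**Parameters.** k defaults to 200 mN/m (midpoint of the 100–300 mN/m
bilayer range); Γ₀ defaults to the 0 µg/mL data point (1.7 mN/m in the
packaged tables); particle radius R = 0.5 µm is carried for bookkeeping
but drops out of the coarse-grained energy. ζ is stored negative
(attraction); formulas use |ζ|. The identity 1 mJ/m² = 1 mN/m makes
ζ = εn₀/k dimensionless.

**Coverage.** The measured adsorption isotherm is not tabulated in the
source, so concentration maps to coverage through a parametric Langmuir
stand-in φ(c) = φ_max·c/(K + c). φ_max is fixed at 1.0 by default to break
the exact (φ_max, ζ) scale degeneracy. Consequence, stated openly: fitted
ζ magnitudes are calibration-dependent and are validated by curve
reproduction and cross-condition ordering, not by exact equality with any
published point value.

**Per-series fit.** `TensionCurveModel` minimises weighted squared
residuals (weights 1/σ²) over (|ζ|, K) with bounds |ζ| ≤ 1 and
K ∈ [1, 10⁵] µg/mL. The K upper bound is deliberately generous: near-linear
tension series live in the dilute-coverage regime K ≫ c_max, and a tighter
cap biases the endpoint prediction. Because ΔΓ(φ) has a kink at φ = |ζ|,
gradient descent alone is unreliable; the optimiser is a dense vectorised
log-grid scan seeded from per-K-column champions, iterative grid zoom, and
a final smooth polish. Two conventions resolve flat directions: (i) when
the best curve lies entirely in the hemisphere-capped regime, |ζ| is only
bounded from below by the data and the reported value is the smallest
magnitude producing the identical curve; (ii) equal-χ² ties prefer the
smaller |ζ|. Reduced χ² is reported with n − 2 degrees of freedom
(n − 3 when Γ₀ is fitted).

**Shared-coverage joint fit.** Experimentally the adsorption isotherm is a
property of the particle batch, measured once — not of each incubation
condition. `fit_tension_table` therefore fits one shared K across a set of
series (e.g. the nine conditions of one plastic) with a separate ζ per
series, by exhaustive scan over K with closed-form ζ profiles and
iterative zoom. Adhesion magnitudes fitted this way are directly
comparable across conditions; with per-series calibrations they are not
(a series that saturates early at a low plateau maps to a weak |ζ| at its
own calibration, which reverses some cross-condition comparisons). On the
packaged tables the shared-calibration fit ranks every
pollutant-incubated condition above the bare (PBS) baseline for all three
plastics, with hexane-to-bare adhesion ratios of ≈ 6.

## Diffusion analysis

MSD uses overlapping-pair time averaging pooled over the ensemble (maximal
pair usage, lower variance than independent increments), up to a default
0.25 of the shortest track; tracks shorter than 10 points are excluded
with a warning. The diffusion coefficient comes from a weighted
through-origin fit of ⟨r²⟩ = 4Dτ over lags 2–10 frame intervals by
default — below that, localisation noise (a constant 4σ_loc² offset)
dominates; above it, pair statistics thin out. The anomalous exponent is
the log–log slope over the same window. `stokes_einstein_diffusion`
returns k_B T/(3πηd); for a 1 µm sphere in water at 25 °C this is
0.49 µm²/s, the bulk scale against which membrane-bound diffusion
(≈ 0.6 µm²/s in the motivating experiments) is judged.

## Synthetic data

Each generator is the exact forward model of one estimator plus Gaussian
noise, with a single integer seed through a local `default_rng` stream:

* tension series: model curve + σ = 0.2–0.5 mN/m (the tables' error
  scale), homoscedastic per series;
* DiB angles: exact inverse angle + angular noise (default 2°), clipped
  to [0°, 180°);
* drop contours: integrated profile + coordinate noise (default scale
  µm), x clipped at the axis, re-sorted by z;
* Brownian tracks: per-axis steps N(0, 2DΔt) plus independent
  localisation noise.

What they do not emulate: drifting baselines and slow adsorption kinetics
in tensiometer traces, optical distortion and needle reflections in
contours, heteroscedastic and correlated replicate errors, motion blur and
track-linking errors, and any real adsorption-isotherm shape beyond
Langmuir. Passing recovery tests therefore demonstrates estimator
correctness and noise robustness at experimental scales, not immunity to
systematic instrument effects.

The packaged tables ship as three CSVs (checksummed in the test suite)
with 27 series over concentrations {0, 50, 100, 150, 300, 500} µg/mL. The
"PA" rows were measured on PMMA microbeads as a stand-in for polyamide;
the label follows the source tables.

## Problem sizes and tolerances in the test suite

Recovery suites use 100 seeds for noisy pendant-drop fits (2 µm contour
noise, tolerance: median 3 %), 50 seeds for ζ recovery at σ = 0.3 mN/m
(median 15 %; 10 % at σ = 0.2), a 100-track × 1000-step ensemble for
diffusion (5 %, exponent 1 ± 0.05), and 1000 random draws for the
wrapping-law oracle (10⁻⁸ in u). These sizes keep the full suite around a
minute of compute while leaving comfortable statistical margins.

## Known limitations

* No Helfrich bending energetics, pore formation, or rupture kinetics;
  the stretching model is quasi-static and mean-field in coverage.
* The Langmuir stand-in cannot represent cooperative or multilayer
  adsorption; fitted (ζ, K) absorb any such misfit.
* Whole-profile pendant fitting may respond to noise differently from
  instrument firmware that uses shape-parameter tables.
* Particle detection and trajectory linking are out of scope; the
  tracking module consumes track tables.
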