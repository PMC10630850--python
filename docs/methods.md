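# Methods

## Scope and data model

The package analyses thin-layer foam-mat drying of a plant purée (red
beetroot pulp foamed with ovalbumin/methylcellulose/maltodextrin) and the
quality of the resulting powder.  Three stages share a small set of typed
containers: `DryingCurve` (time/moisture observations at one air
temperature), `SimulationConfig`/`SimulationResult` (transport-model input
and the space–time fields it produces), and the powder measurement/colour
dataclasses.  All internal units are SI with temperatures in °C; times are
stored in seconds, while drying rates are reported per minute, the
convention of the tabulated summaries.

## Drying kinetics

Moisture ratio is MR = (X−X_e)/(X_i−X_e); when the equilibrium moisture is
negligible next to X the simplified MR = X/X_i is used (the package
default, matching common practice).  The estimation chain assumes
falling-rate, diffusion-limited drying of an infinite slab of thickness L
dried from one face, for which the Crank series gives

MR(t) = (8/π²) Σ_{N≥0} (2N+1)⁻² exp(−(2N+1)²π² D_eff t / 4L²).

`fit_deff` regresses ln MR on t by OLS over points whose MR lies in a
configurable window, default **(0.95, 0.02)**: the upper bound drops the
initial warm-up region where higher series terms still matter (the
one-term model is exact only for MR ≲ 0.6; in practice the bias from
including points up to 0.95 stays well under 2% and the wider window is
more robust for noisy data), and the lower bound drops near-equilibrium
points whose log-noise diverges.  D_eff = −slope·4L²/π².

`fit_activation_energy` regresses ln D_eff on 1/(T+273.15) and returns
E_a = −slope·R (R = 8.314 J/mol K) and D₀ = exp(intercept).  Feeding it
the three study diffusivities (5.218, 7.150, 8.689 ×10⁻⁹ m²/s at
50/60/70 °C) returns E_a ≈ 23.55 kJ/mol.

Drying rates are forward differences |ΔX|/Δt reported as magnitudes,
(kg/kg db)/min; the raw difference is negative during drying and the sign
convention follows the tabulated positive values.

## Thermophysical properties

Foam density, specific heat and thermal conductivity come from the
Choi–Okos component polynomials (water, protein, fat, carbohydrate, fiber,
ash; quadratics in T), bundled as `foamdry/data/choi_okos.csv` and
user-overridable.  The mixing rules are:

- density: ρ = (1−ε)·Σ Xᵢρᵢ by default (`as_printed`), with the
  conventional harmonic form ρ = (1−ε)/Σ(Xᵢ/ρᵢ) available; the two agree
  for single-component input and differ by a few percent for the foam,
- specific heat: mass-fraction-weighted arithmetic mean,
- conductivity: weighted by Xᵢρᵢ and normalised, hence bounded by the
  component extremes.

The coefficient table is validated only through bounded-mixture property
tests (every mixture property must lie between its component extremes),
not through asserted numeric constants.

Air-side values default to the fixed study constants (ρ∞ = 1.073 kg/m³,
c_p∞ = 1005.04 J/kg K, k∞ = 0.0287 W/m K, μ∞ = 19.907×10⁻⁶ Pa s) rather
than temperature-dependent correlations.  Vapor diffusivity in air uses
the empirical form D_AB = (2.26/P)·((T+273.18)/273.18)^1.81 with
P = 101 325 Pa by default; the 273.18 offset is kept verbatim from its
source, while every other °C→K conversion uses 273.15.

## Transfer coefficients

With Re = ρ∞u∞d/μ∞ (d = foam thickness, 0.005 m, by the study's
convention; exposed as a parameter), Pr = c_p∞μ∞/k∞ (standard definition)
and Sc = μ∞/(ρ∞D_AB), the laminar flat-plate correlations
Nu = 0.664 Re^½Pr^⅓ and Sh = 0.664 Re^½Sc^⅓ give h_m = Sh·D_AB/d and,
through the Chilton–Colburn analogy, h = h_m ρ∞ c_p∞ (α/D_AB)^⅔.  The
direct route h = Nu·k∞/d is computed alongside as a diagnostic; with
consistent definitions the two coincide identically, and the test suite
asserts 2% agreement across gas-like Pr, Sc ∈ [0.5, 1.5].  At 70 °C,
u∞ = 1 m/s: Re ≈ 270, h_m ≈ 0.060 m/s, h ≈ 55 W/m² K.

## Transport model

Governing equations on the foam layer (slab of thickness L = 5 mm;
optionally an axisymmetric cylinder of radius 75 mm):

- heat: ρc_p ∂T/∂t = ∇·(k∇T),
- moisture: ∂C/∂t = ∇·(D_eff∇C), C = X·ρ_s/M_w (mol moisture per m³
  foam; ρ_s is the dry-solid density per foam volume).

Initial state: uniform T₀ = 20 °C, X₀ = 3.5657 kg/kg db.  Boundary
conditions:

- exposed surface: heat flux h(T∞−T_s) − q_evap with the evaporative sink
  q_evap = h_m·M_w·φ·(C_s−C_e) (the dimensionally consistent default;
  an `as_printed` variant replaces M_w by ρ∞, reproducing the source
  expression verbatim), moisture flux h_m(C∞−C_s) with C∞ = 0 (dry air)
  by default;
- plate bottom and side wall: temperature pinned at T∞; moisture
  zero-normal-flux (impermeable plate).  A literal variant that freezes
  the bottom concentration in time is available behind
  `literal_bottom_hold` for documentation runs only — it breaks global
  conservation by construction and contradicts the observed bottom
  drying, so the impermeable reading is the default.

D_eff is constant per run (the kinetics estimate for that air
temperature); no moisture-dependent diffusivity.  ρ, c_p, k are
re-evaluated each step from the local temperature and composition (water
fraction w = X/(1+X), dry-component ratios fixed) unless
`property_update="frozen"`.

**ρ_s default.**  The study lists an initial foam density of 0.13778 in
SI-implausible units; read as g/cm³ (137.78 kg/m³) it gives
ρ_s = 137.78/(1+X₀) ≈ 30.18 kg/m³.  This is an explicit config field,
never silently derived, and — because the moisture PDE is linear and
C ∝ ρ_s — the simulated MR trajectories do not depend on it.

**Termination.**  Default duration is the experimental drying time
(6900/5700/5100 s at 50/60/70 °C), treated as an input; an alternative
rule stops when the volume-average moisture reaches a threshold.

## Numerical scheme

Cell-centred finite volumes on a uniform grid (default 50 cells through
the thickness), backward-Euler time stepping (θ-weighted optionally,
θ ∈ [0.5, 1]), default Δt = 30 s.  Robin boundaries are folded into
effective face conductances (series half-cell + film resistance), so the
discrete moisture balance telescopes exactly: the mass-balance residual
reported with every run is |inventory change − time-integrated surface
flux| relative, and lands at machine precision (~10⁻¹³) rather than at a
scheme-dependent tolerance.  Coefficients are lagged one step (single
Picard iteration).  The axisymmetric mode assembles sparse operators with
cell volumes r·Δr·Δx and solves with a direct factorisation.

Two guards handle pathological steps:

- a physical-bounds check (moisture within [min(C∞, C_e), C₀]; temperature
  within [min(T₀,T∞)−ε_c, T∞] with ε_c the configurable transient-cooling
  margin, default 10 °C) triggers automatic step halving, with failure
  after 10 halvings;
- an **evaporative-sink limiter**: the surface term is singular at
  startup — a still-wet surface implies a latent-heat flux of order
  MW/m² for a transient lasting ~D_eff/h_m² (microseconds), which coarse
  steps never resolve but fine steps do, driving an unbounded local
  undershoot.  The sink is therefore capped at the flux that would bring
  the surface cell to the cooling floor within the substep.  The limiter
  is inactive at production resolution (default grid and step) and its
  activation is logged.

The backward-Euler O(Δt) error dominates the O(Δx²) spatial error by
roughly two orders of magnitude at the defaults, so
`grid_time_convergence` refines time by 4× and space by 2× per level;
on the 70 °C case four levels give successive final-moisture changes of
4.1% → 1.1% → 0.27%, i.e. the finest pair agrees to better than 0.5%.
Verification against the analytic Crank series (surface effectively
pinned at equilibrium via a very large h_m, constant properties, ambient
concentration set to the equilibrium level, 200 cells, 2 s steps) shows
the volume-average MR within 0.4% of the 50-term series for Fo > 0.05 at
all three temperatures.  In that limit configuration the temperature
field is a by-product (the artificial h_m implies an equally artificial
sink) and the cooling-margin check is disabled.

## Powder quality

Densities are mass/volume ratios (bulk: poured, tapped: settled,
particle: toluene displacement); porosity ε = 1−ρ_B/ρ_P; Carr index
CI = 100(ρ_T−ρ_B)/ρ_T and Hausner ratio HR = ρ_T/ρ_B (the identity
CI = 100(1−1/HR) holds exactly).  Flowability class bands contain printed
gaps (e.g. CI between 10 and 11); each band's upper edge is extended to
the next band's lower edge, half-open [low, next_low), so classification
is total and deterministic — CI = 10.386 classifies "Excellent".

Colour indices from CIELAB triplets: ΔE is the Euclidean distance to a
required reference triplet (no default reference is fabricated); chroma
C* = √(a*²+b*²); hue uses the quadrant-aware arctangent in degrees
(undefined, returned as missing, for a* = b* = 0); the browning index is
the standard chromaticity-ratio form BI = 100(x−0.31)/0.17 with
x = (a*+1.75L*)/(5.645L*+a*−3.012b*) — a reconstruction of a
typographically garbled source expression, validated by agreement with
the published BI column to 0.01 at 50 °C and to <0.5% at all three
temperatures.

Indices may be computed per replicate then averaged, or from mean inputs;
the two differ in the third decimal for ratio quantities (e.g. the HR
drop from 50→70 °C is 1.67% averaging per-replicate ratios but 1.78%
recomputed from mean densities), which accounts for the small
discrepancies among published summary rows.

## Synthetic data

`generate_drying_curve` builds X(t) = MR·(X₀−X_e)+X_e from the Crank
series (n-term; 1 reproduces the log-linear model exactly) or from a full
solver run, plus additive Gaussian noise clipped at zero.
`generate_replicates` draws Gaussian replicate tables around the study's
mean ± SD quality values (triplicate by default), clipped to physical
ranges — clipping biases means slightly when an SD is comparable to the
distance to a bound, negligible at the study SDs.
`generate_temperature_series` produces exponential-approach foam
temperature traces.  All generators are seeded and bit-reproducible.

What the generators deliberately do not emulate: foam microstructure and
its evolution (bubble collapse, crust formation), shrinkage, instrument
drift, or autocorrelated measurement error.  Passing recovery tests on
this synthetic structure shows the estimation chain is consistent and
noise-robust under the stated noise model; it does not validate the
transport model against real drying curves, for which the study's own
experimental comparison (not redistributable here) is the reference.

Round-trip and calibration tests fit with the full MR form using the
generator's known X_e, since the synthetic ground truth includes the X_e
offset; the simplified form would contribute a ~3% bias that is a
property of the normalisation, not of the estimator.  With noise SD 0.05
(dry-basis) on 30 points, the fitted D_eff lands within 10% of truth in
98% of 200 seeded repetitions.

## Known limitations

- No shrinkage, porosity evolution, sorption isotherms, radiation, or
  conjugate air-flow modelling; ε is a fixed input.
- The evaporative term lacks humidity/temperature feedback (no wet-bulb
  closure), hence the startup singularity described above; end-state
  bottom moistures are therefore qualitative (simulated 0.061 at 70 °C
  at default resolution) rather than validated quantities.
- Whether ρc_p sits inside or outside the time derivative as composition
  evolves is treated quasi-statically (coefficients frozen within a
  step).
- The ln MR fit window is a package choice; the source analysis does not
  state which points entered its regression.
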