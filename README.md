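# foamdry

Drying-kinetics analysis, coupled heat–moisture simulation, and powder
quality metrics for **foam-mat drying** of plant foods — the process in
which a purée (here, red beetroot pulp) is whipped into a stable foam,
spread as a thin layer (≈5 mm) on a plate, and dried in hot air at moderate
temperatures (50–70 °C) to produce a pigment-rich powder.

The package serves food-process engineers who need to

1. **characterise drying kinetics** from time/moisture-content tables:
   moisture ratio MR = (X−X_e)/(X_i−X_e), drying rate, the effective
   moisture diffusivity D_eff per air temperature via the Crank-slope
   method, and the Arrhenius activation energy E_a across temperatures;
2. **simulate the drying layer** as a coupled conduction–diffusion problem
   with convective heating, evaporative cooling and convective moisture
   loss at the exposed face; and
3. **evaluate the resulting powder**: bulk/tapped/particle densities,
   porosity, Carr index and Hausner ratio with flowability classes, water
   absorption/solubility, moisture content, and CIELAB colour indices
   (ΔE, chroma C\*, hue angle H°, browning index BI).

## The models

**Kinetics.** In the falling-rate period the layer behaves as a diffusion-
limited slab.  The Crank series for one-face drying,

    MR(t) = (8/π²) Σ_{N≥0} (2N+1)⁻² exp(−(2N+1)² π² D_eff t / 4L²),

reduces at long times to its first term, so ordinary least squares of
ln MR on t gives D_eff = −slope·4L²/π².  Across air temperatures
D_eff = D₀ exp(−E_a/RT), so a second regression of ln D_eff on 1/T gives
the activation energy.

**Transport.** Inside the foam, ρc_p ∂T/∂t = ∇·(k∇T) and
∂C/∂t = ∇·(D_eff ∇C), with C the molar moisture concentration
(C = X·ρ_s/M_w).  The exposed face exchanges heat h(T∞−T_s) minus a
latent-heat sink, and moisture h_m(C∞−C_s); the plate bottom is held at
the air temperature and is impermeable.  Foam ρ, c_p and k follow
Choi–Okos composition/temperature polynomials; h and h_m come from
laminar flat-plate correlations (Nu = 0.664 Re^½ Pr^⅓ and its Sherwood
analogue) plus the Chilton–Colburn analogy.  Discretisation is
cell-centred finite volumes with implicit time stepping; the discrete
moisture balance telescopes exactly, so the reported mass-balance
residual is a genuine conservation check.

## Worked example

```python
import numpy as np
from foamdry import (AirStream, SimulationConfig, fit_activation_energy,
                     fit_deff, simulate)
from foamdry.synthetic import CurveGenSpec, generate_drying_curve

# synthetic falling-rate curves at the three study temperatures
fits = {}
for T, deff, dur in [(50, 5.218e-9, 6900), (60, 7.150e-9, 5700),
                     (70, 8.689e-9, 5100)]:
    curve = generate_drying_curve(CurveGenSpec(
        deff=deff, air_temperature=T, times=np.arange(0, dur + 1, 240.0)))
    fits[T] = fit_deff(curve, xe=0.01, simplified=False)
    print(f"{T} degC: D_eff = {fits[T].deff:.3e} m2/s  (r2 = {fits[T].r_squared:.5f})")

arr = fit_activation_energy([(T, f.deff) for T, f in fits.items()])
print(f"E_a = {arr.ea/1000:.2f} kJ/mol")

result = simulate(SimulationConfig(air=AirStream(temperature=70.0)))
print(f"final average moisture: {result.average_moisture[-1]:.4f} kg/kg db")
print(f"bottom / surface: {result.bottom_moisture[-1]:.4f} / "
      f"{result.surface_moisture[-1]:.5f} kg/kg db")
print(f"mass-balance residual: {result.mass_balance_residual:.1e}")
```

prints

```
50 degC: D_eff = 5.238e-09 m2/s  (r2 = 0.99995)
60 degC: D_eff = 7.171e-09 m2/s  (r2 = 0.99997)
70 degC: D_eff = 8.708e-09 m2/s  (r2 = 0.99998)
E_a = 23.48 kJ/mol
final average moisture: 0.0385 kg/kg db
bottom / surface: 0.0605 / 0.00095 kg/kg db
mass-balance residual: 9.2e-14
```

The fitted diffusivities recover the generating values to well under 1%,
the activation energy lands at 23.5 kJ/mol (the value the three
diffusivities imply), and after the 85-minute run at 70 °C the layer is
nearly dry with the expected bottom-to-surface moisture gradient and a
machine-precision moisture balance.

## Command line

```bash
foamdry synth    --config cfg.yaml --seed 7 --out out/   # synthetic data
foamdry kinetics --config cfg.yaml --out out/            # D_eff + E_a report
foamdry simulate --config cfg.yaml --out out/            # field snapshots + report
foamdry quality  --config cfg.yaml --out out/            # powder metrics table
```

Configuration is YAML with one section per subcommand; unknown keys are
rejected by name, and every output directory receives a manifest
sufficient to regenerate it exactly.

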