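# leafheat

Estimating the specific heat capacity of plant leaves from thermal-camera
temperature transients.

## The problem

Thermography infers transpiration and stomatal conductance from leaf
temperature, but under fluctuating light the leaf's *thermal inertia*
enters the energy balance through the areal heat capacity

    k = lt · ρ · C_p        (J m⁻² K⁻¹)

— thickness × density × specific heat capacity.  C_p (J kg⁻¹ K⁻¹) is
poorly tabulated for leaves, and the classical ways to measure it
(calorimetry, photothermal probing) are destructive or slow.  A faster
route: expose the leaf to a short light pulse with known absorbed
irradiance, record the temperature transient with a thermal camera, and
fit the dynamic energy-balance model

    k dT_leaf/dt = α I_s + 2εθ(T_reflect⁴ − T_leaf⁴)
                 − 2ρ_air C_s g_bh (T_leaf − T_air)
                 − 2λ (0.622 ρ_air/P_atm) · [1/(1/g_sw + 1/g_bw)] · VPD

for k together with the boundary-layer (g_bh) and stomatal (g_sw)
conductances.  Since ρ·lt is just fresh weight over leaf area,
C_p = k/(ρ·lt) follows with its full posterior uncertainty.  This package
implements the forward simulator, the Bayesian inversion (MCMC with
convergence diagnostics), the accompanying trait calculators (leaf water
content, SLA/LMA, reference-emittance emissivity), and the ±10%
input-sensitivity analysis — all testable end-to-end on synthetic
transients because no instrument data are redistributable.

It is intended for plant ecophysiologists and phenotyping engineers who
run pulse-protocol thermography and want calibrated C_p estimates with
honest uncertainties.

## Worked example

Recover the heat capacity of a black-painted aluminum plate
(lt = 1.335 mm, ρ = 2484 kg m⁻³, true C_p = 896 J kg⁻¹ K⁻¹) from a
synthetic replica of its validation run — 60 s pulse at 270 W m⁻², 9 min
dark, 0.05 K camera noise:

```python
import leafheat as lh
from leafheat import datasets

fx = datasets.make_aluminum_fixture(seed=1)          # synthetic 25 Hz trace
res = lh.fit_transient(
    fx.trace, fx.protocol, fx.env, fx.sample.optics,
    mcmc=lh.MCMCConfig(seed=7, walkers_per_chain=8, solver_dt=0.25),
    mass_per_area=fx.sample.mass_per_area,           # = lt * rho
    fix_g_sw=0.0,                                    # a dry plate does not transpire
)
print(f"C_p  = {res.mean['C_p']:.1f}  95% CI "
      f"[{res.ci_low['C_p']:.1f}, {res.ci_high['C_p']:.1f}] J/kg/K")
print(f"g_bh = {res.mean['g_bh']:.4f} m/s   RMSE = {res.rmse:.3f} K   "
      f"converged = {res.converged}")
```

```
C_p  = 896.3  95% CI [893.3, 899.2] J/kg/K
g_bh = 0.0100 m/s   RMSE = 0.049 K   converged = True
```

The posterior mean lands within 0.1% of the plate's tabulated value, the
95% credible interval covers it, and the residual RMSE equals the injected
sensor noise — the transient carries no unexplained structure.  The same
call without `fix_g_sw` fits all three parameters for a transpiring leaf,
and `lh.cp_sensitivity_table` refits with each assumed input perturbed by
±10% to quantify how an irradiance, temperature or absorptance bias would
propagate into C_p.

A command-line interface wraps the same library:

```
leafheat make-fixtures --out fixtures/          # packaged synthetic datasets
leafheat fit config.yaml --trace-csv run.csv    # JSON fit report
leafheat sensitivity config.yaml --trace-csv run.csv
leafheat traits table.csv                       # LWC / SLA_FW / LMA columns
leafheat emissivity 40.0 38.85 20.0             # reference-emittance estimate
```

## Layout

- `leafheat.physics` — psychrometrics, flux terms, ODE right-hand side,
  steady state
- `leafheat.simulate` — protocols, adaptive/compiled integrators,
  synthetic traces, heating slope, spline derivative, onset detection
- `leafheat.inference` — priors, posterior, MCMC fit, C_p derivation,
  R̂/ESS diagnostics
- `leafheat.traits` — LWC, mass-per-area/SLA/LMA, water loss, emissivity
- `leafheat.sensitivity` — ±10% one-at-a-time refits and the bar chart
- `leafheat.io` / `leafheat.cli` — CSV/YAML/JSON formats and the `leafheat`
  command
- `leafheat.datasets` — the packaged synthetic study designs

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
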