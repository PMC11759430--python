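# Methods

## The model

A leaf (or a reference plate) exchanges energy with its surroundings through
four routes: absorbed short-wave radiation, net long-wave radiation,
sensible heat, and latent heat.  Away from steady state, the imbalance
changes the object temperature at a rate set by its areal heat capacity
k = lt·ρ·C_p (J m⁻² K⁻¹):

    k dT_leaf/dt = α I_s
                 + 2 ε θ (T_reflect⁴ − T_leaf⁴)
                 − 2 ρ_air C_s g_bh (T_leaf − T_air)
                 − 2 λ (0.622 ρ_air / P_atm) g_tot (es(T_leaf) − RH_air es(T_air))

with g_tot = 1/(1/g_sw + 1/g_bw) and g_bw = g_bh/0.92.  Short-wave
radiation is absorbed on the illuminated face only; long-wave, sensible and
latent exchange act on both faces, hence the factor 2.  T_reflect is the
radiative temperature of the surroundings, measured in practice from a
crumpled aluminum foil imaged with emissivity set to 1.

The measurement exposes the sample to a short light pulse (10 s at
270 W m⁻² for leaves; 60 s for a high-inertia metal plate) followed by
darkness, while a thermal camera records T_leaf at 25 Hz.  The rise is
dominated by αI_s/k, the relaxation by the conductances; fitting the whole
transient identifies (k, g_bh, g_sw) jointly.  C_p follows as
k/(ρ·lt), with ρ·lt measured simply as fresh weight over one-sided leaf
area.

### Psychrometric conventions

Saturation vapour pressure uses the Tetens formula over liquid water,
es(T) = 610.78·exp(17.27 t_C/(t_C + 237.3)) Pa; air density follows the
ideal-gas law at (T_air, P_atm); the humid-air heat capacity
C_s = 1010 J kg⁻¹ K⁻¹ and latent heat λ = 2.45×10⁶ J kg⁻¹ are fixed 20 °C
coefficients.  All three choices are second-order for this application
(they scale loss terms that the conductance estimates absorb) and all are
overridable in the run configuration.  g_sw = 0 is a valid input: the
series conductance is defined as 0 there (transpiration pathway blocked),
which is what makes a dry plate a legal sample rather than a division
error.

## Inference

The posterior over (k, g_bh, g_sw, σ) — σ the residual noise sd — combines
a Gaussian likelihood of the observed minus integrated model temperature
with half-normal priors truncated to the nonnegative half-line:
sd 0.005 m s⁻¹ for both conductances (weakly informative at the scale of
measured leaf values), sd 5000 J m⁻² K⁻¹ for k (covers metal plates and
the full leaf range), sd 0.5 K for σ.  For a dry reference plate g_sw is
pinned to 0.

Two nuisance choices matter:

* **Initial temperature.**  The first camera sample carries sensor noise,
  and an error in T(0) relaxes only over the thermal time constant, so
  anchoring the solution at the raw first observation biases k by a few
  posterior standard deviations.  The initial temperature is therefore
  estimated: a smoothing-spline evaluate-at-origin provides the anchor and
  a δT0 offset with a Normal(0, 0.2 K) prior is marginalized in the MCMC.
* **Observation rate.**  25 Hz traces are decimated to 5 Hz for fitting.
  The dynamics are slow (time constants ≥ 20 s) and the noise is white, so
  the information loss is negligible while the likelihood cost drops
  fivefold.

Sampling uses an affine-invariant ensemble (emcee) with differential-
evolution moves, run in log-transformed parameter space (the Jacobian is
included) — positivity is built in and scale parameters mix better.  A
Nelder–Mead refinement of a moment-style starting point (k from the onset
slope αI/(dT/dt), g_bh from the decay time constant) locates the mode, and
walkers initialize from the Laplace approximation there, so warmup only
explores the local posterior.  The budget is 4 walker-groups × 12 walkers
× 1000 iterations with the first 500 discarded.  Convergence requires
rank-normalized split-R̂ < 1.01 and ESS > 200 for every free parameter
(walker groups play the role of chains); failing fits are flagged, never
silently returned.  A protocol without a light pulse leaves k unidentified;
this is detected up front and surfaces as a prior-wide interval plus a
warning.

### Forward solvers

The public simulator integrates the ODE with an adaptive Runge–Kutta
(scipy RK45, rtol = atol = 1e-8), restarted at every light-segment
boundary so the step controller never straddles the irradiance
discontinuity.  The likelihood's inner loop is a numba-compiled fixed-step
RK4 on a pre-built grid (default 0.1 s; 0.25 s for the slow plate) with
the environment drivers pre-interpolated at nodes and half-nodes.  With
thermal time constants of 20–90 s the discretization error is orders of
magnitude below sensor noise; both solvers are cross-validated against
each other and against an independent plain-Python RK4 at dt = 1 ms in the
test suite (agreement < 1 mK).

## Synthetic data

No instrument traces are redistributable, so validation runs on synthetic
replicas of the two study designs, generated by the reference integrator
plus i.i.d. Gaussian sensor noise of sd 0.05 K — between the camera noise
floor (NETD < 30 mK) and typical thermocouple noise (~0.2 K):

* **Aluminum plate**: thickness 1.335 mm, density 2484 kg m⁻³,
  C_p = 896 J kg⁻¹ K⁻¹ (so k ≈ 2971 J m⁻² K⁻¹), α 0.98, ε 0.96, g_sw = 0;
  60 s pulse at 270 W m⁻² then 9 min dark.
* **Leaf**: k = 900 J m⁻² K⁻¹, g_bh = 0.01 m s⁻¹, g_sw = 0.002 m s⁻¹,
  α 0.92, ε 0.97, tomato-like fresh mass per area 0.2467 kg m⁻²; 10 s
  pulse then 110 s dark.

Both sit in a dark enclosure at the 20 °C lab setpoint with
T_reflect = T_air, RH 50% (the enclosure humidity was not specified; 50%
is a typical conditioned-lab value and is irrelevant for the transpiration-
free plate), standard pressure, environment logged at the 5 s sensor
cadence.  g_bh = 0.01 m s⁻¹ corresponds to the fan-mixed enclosure
(~0.2 m s⁻¹ wind over ~5 cm frames).  What the synthetic data do **not**
emulate: slow drifts of the enclosure air, spatial irradiance
inhomogeneity across the sample, camera calibration error, and emissivity/
absorptance measurement error.  Passing tests therefore demonstrate the
correctness and calibration of the inversion under the stated noise model,
not the field accuracy of the instrument chain.

## Sensitivity analysis

The ±10% one-at-a-time analysis holds the observed trace fixed, perturbs
one *assumed* input (absorptance, emissivity, T_reflect, irradiance,
T_air, relative humidity, thickness), refits the full model with the same
seed, and reports the relative change of the posterior-mean C_p.
Temperatures are perturbed on the Celsius scale (±10% of a kelvin value
would be a ±30 K absurdity, and ±10% of ~20 °C is the ∓2 K scale of a
plausible sensor bias); all other factors scale on their natural scale.
Thickness enters only through ρ·lt, so its effect is the exact reciprocal
rescaling C_p → C_p/(1 ± 0.1).  Computing by full refit rather than local
derivative matches the experimental procedure and captures the parameter
compensation (g_bh re-equilibrating against a mis-assumed temperature)
that a derivative would miss.

On the synthetic plate the pattern is: irradiance and absorptance
±10.0%, thickness −9.1/+11.1%, humidity and emissivity < 0.1%, and large
positive responses to colder assumed temperatures (T_air −10% → ≈ +39%,
T_reflect −10% → ≈ +97% under these idealized isothermal conditions; see
Limitations).

## Numerical choices

* Equilibrium temperature: Brent root-finding in [T_air − 30, T_air + 50] K,
  residual < 1e-10 K s⁻¹; the rhs is strictly decreasing in T_leaf, so the
  root is unique for g_bh > 0.
* Smoothing-spline derivative: cubic smoothing spline with
  generalized-cross-validation penalty; the derivative of the fitted
  function is exact.  The GCV default is a pragmatic choice — any
  criterion that suppresses noise without flattening the pulse transient
  works, and the penalty is exposed.
* Light-onset detection: earliest sample where the smoothed derivative of
  a fast-responding reference (black tape) trace exceeds a threshold
  (default 0.05 K s⁻¹).
* Heating slope: maximum temperature rise inside the pulse window divided
  by the exposure time.
* Degenerate inputs: duplicated timestamps and non-monotone time axes are
  parse errors naming the line; DW > FW, negative conductances and
  nonpositive k are domain errors; a missing dry weight propagates as an
  explicit missing value through LWC/LMA.

## Limitations

* The synthetic environment is exactly constant and exactly isothermal
  (T_reflect = T_air).  This maximizes the leverage of the long dark tail
  on the assumed-temperature sensitivities: a −2 K bias in T_air or
  T_reflect forces the refit to re-pin the observed equilibrium by moving
  g_bh, and k follows the decay-rate compensation.  The resulting
  magnitudes (+39%/+97%) are therefore upper-end; with measured, drifting
  environment traces and a real air–foil temperature split the published
  experiment reports the same sign and ordering at smaller magnitude.
* Conductances are treated as constant over the 2–10 min protocol;
  stomata are assumed not to react within the pulse.
* The model is zero-dimensional: no within-leaf temperature gradients, no
  view-factor radiation geometry, no angle-dependent absorptance.
* σ is modelled as white Gaussian noise; correlated camera drift would
  narrow the credible intervals artificially.
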