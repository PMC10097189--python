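# Methods

## Models

**Planar (Cottrellian) transient.** After a potential step at a planar
macroelectrode under semi-infinite linear diffusion, the Faradaic current is
I(t) = n F A c √(D/π) · t^(−1/2). The lumped amplitude B₀ = n F A c √(D/π)
(units A s¹ᐟ²) is the single fitted parameter; n is the number of exchanged
electrons (2 for glucose → gluconolactone at gold), F the Faraday constant
(96485.33 C mol⁻¹), A the electroactive area (m²), c the bulk concentration
(mol m⁻³) and D the diffusion coefficient (m² s⁻¹; 6.7 × 10⁻¹⁰ for glucose in
aqueous solution at room temperature). The evaluator rejects t ≤ 0, where the
expression is singular; generated grids therefore start at t_min = 0.1 s by
default.

**Convergent diffusion.** An isolated hemisphere of radius r has the
steady-state limit current I = 2π r n F D c. A microdisk follows
I = 4 n F r D c · f(τ) with the Shoup–Szabo interpolation
f(τ) = 0.7854 + 0.8862 τ^(−1/2) + 0.2146 exp(−0.7823 τ^(−1/2)) and
τ = 4 D t / r², which recovers the Cottrellian t^(−1/2) behavior at short
times and tends to 1 (the convergent steady state) as τ → ∞. An array of N
disks of average radius r within total area A is evaluated as
I = N · 4 n F A D c / (π r) · f(τ). The grouping of that prefactor — and the
reading of A as the *total* electrode area rather than per-disk area — is a
package convention adopted because the per-disk quantities N and r are not
separately measurable for dewetted nanostructures; only the lumped prefactor
is identifiable, which is also why the biexponential amplitudes below are
fitted as free currents.

**Kinetic transient.** Electrodes whose features are comparable to the
diffusion length do not follow the diffusive models; their transients are
fitted by the two-phase exponential decay
I(t) = a₁ + a₂ e^(−k₁ t) + a₃ e^(−k₂ t) (k₁ > k₂ > 0), the analytic signature
of second-order formation of an adsorbed glucose intermediate on oxidized
gold followed by its first-order decay to gluconolactone. a₁ is the
diffusion-limited steady-state current reached once adsorbed glucose is
consumed; I(0) = a₁ + a₂ + a₃.

**Butler–Volmer density.** The anodic branch
J(E) = k₀ F c exp(α_a F (E − E_f⁰) / (R T)) is provided as a forward
evaluator only (no fit), since peak-potential data sufficient to constrain
(k₀, α_a, E_f⁰) are not bundled with the package.

**Regime classifier.** The diffusion length δ̄ = √(2 D t) at a transient
time scale t (default 1 s) is compared with the electrode feature radius;
ratio ≤ 0.1 (default, configurable) selects the Cottrell model, otherwise the
biexponential. A `delta_override` argument substitutes an externally supplied
diffusion length: reported transient diffusion lengths for this system
(≈ 2.8 μm at sub-second times) are an order of magnitude below √(2Dt) with
the glucose D above, and the package does not guess which convention produced
them — it computes √(2Dt) verbatim and lets the user impose a different
value.

## Fitting

All fits are unweighted least squares (no replicate-variance information is
available for single transients). The Cottrell model is linear in B₀, so the
exact minimizer B₀ = Σ(i/√t) / Σ(1/t) is computed in closed form; the
iterative Levenberg–Marquardt path (lmfit) starts there (or from a
user-supplied value) and is cross-checked against the closed form in the test
suite at 1e−8 relative.

The biexponential fit enforces k₁ > k₂ > 0 and a₁ ≥ 0 by parametrizing
k₁ = k₂ + Δk with bounds k₂ > 0, Δk ≥ 0 — no constrained solver is needed,
and a start with swapped rate labels is re-ordered (amplitudes following
their rates) so the canonical ordering is always returned. Default
initialization is curve peeling: the steady state from the mean of the last
10% of samples, the slow rate from a log-linear fit of the excess current
over a mid-to-late window, the fast rate from the early-time remainder after
subtracting the slow phase. Convergence tolerances are 1e−10 on the relative
SSR change with generous evaluation caps (500-iteration scale); transients of
a few thousand samples fit in milliseconds. Degeneracies are reported rather
than failed: a collapse Δk → 0 emits a warning and a diagnostic flag, and a
transient amplitude below 0.1% of the steady state adds a reduced-model
suggestion to the diagnostics. Goodness of fit is the adjusted R²,
1 − (1 − R²)(n − 1)/(n − p − 1).

Standard errors come from the Jacobian-based covariance at the optimum; the
error on the derived k₁ = k₂ + Δk combines var(k₂), var(Δk) and their
covariance. On noiseless synthetic data these are numerically zero.

## Synthetic data

The generator emulates what the analysis assumes about real acquisitions:
transients on a 0.1–150 s grid (0.1 s step, matching the instrument window;
the first 100 ms after the step are excluded as dominated by double-layer
charging and the t = 0 singularity), noiseless model evaluation plus optional
seeded Gaussian noise, either additive (σ in A) or proportional (σ as a
fraction of signal). All randomness flows from the `NoiseSpec` seed. The
published parameter sets for the four electrode types — nanoporous,
thermally dewetted 8 nm/300 °C and 17 nm/400 °C, laser-dewetted — are shipped
as constants (`CHRONO_PARAMS`, `CALIBRATION_PARAMS`) and are the default
generating truths.

What it does *not* emulate: double-layer charging spikes, drift, mains
pickup, convective noise at long times, or electrode fouling. Passing the
parameter-recovery tests therefore shows that the estimators are correct and
well-conditioned on the models' own terms, not that the models describe any
particular measured electrode.

The surface-kinetics simulator integrates the coverage balance
dθ/dt = k₁ c (1 − θ) − k₂ θ with θ(0) = 0 and current
i = n F A Γ_tot k₂ θ (Γ_tot the active-site density, mol m⁻²). This is the
package's minimal kinetic reading of the adsorption/decay scheme: bilinear
(second-order) formation in free sites and glucose, first-order decay, with
the measured current carried by the decay step. Under constant excess glucose
the ODE is linear with the closed-form relaxation
θ(t) = θ_ss (1 − e^(−(k₁c+k₂)t)), θ_ss = k₁c/(k₁c+k₂), used as the
integrator's oracle (LSODA, rtol 1e−10/atol 1e−12; agreement required at
1e−8). The simulator is a didactic companion to the biexponential fit, not a
stage chained into trace generation — the biexponential already lumps the
kinetic and diffusive contributions, and how they would superpose at early
times is not defined by the scheme alone.

## Calibration

Steady-state current density versus concentration is fitted by ordinary
least squares in the presentation units of the field (μA cm⁻², mM); no
weighting is applied because one point per concentration level is the
assumed design. At least 3 points with non-zero concentration variance are
required. Inverse read-out x = (j − a)/b errors out at zero sensitivity.

## Problem sizes

Recovery runs use the full 1500-point acquisition grid (0.1–150 s at 0.1 s)
and 4-point calibration lines at 2.5, 5, 7.5, 10 mM; the Monte-Carlo bias
check uses 1000 noise replicates at σ = 10 μA through the closed-form
estimator. Each recovery completes in well under a second.

## Known limitations

- The two-phase decay amplitudes are reported as lumped currents; the
  decomposition into per-disk quantities requires N, A, r to be known
  independently, which dewetted nanostructures do not provide.
- No LOD/LOQ estimation (no blank-noise model) and no interference
  correction; selectivity is outside the package's scope.
- The regime classifier is a scalar heuristic on one feature length; real
  nanostructure ensembles have size *distributions*, and electrodes near the
  threshold may need both fits compared explicitly.
- Adjusted R² on synthetic noiseless data is exactly 1 and carries no
  information about experimental noise levels.
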