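# Methods

## Model

`mainferm` simulates isothermal batch wine fermentation as two coupled
steps. The growth step consumes assimilable nitrogen N with a
ratio-dependent (Contois) specific rate μ_N(N, X) = μ_N_max·N/(N + K_N·X),
chosen over Monod because growth is observed to slow under biomass excess.
Nitrogen consumption exceeds what biomass synthesis accounts for; the
excess is modeled as maintenance proportional to growth activity,
m(N, X) = α(N)·μ_N(N, X) with α(0) = 0. Tying maintenance to growth
activity (rather than a constant) guarantees dN/dt = 0 at N = 0, so
nitrogen cannot be driven negative after exhaustion — the known failure
mode of constant-maintenance batch models. Substituting
y(N) = Y/(1 + α(N)·Y) with Y = y(0) turns the balance into the equivalent
variable-yield form dN/dt = −μ_N·X/y(N); both formulations are implemented
and their numerical agreement is a test, not an assumption.

The sugar step produces ethanol and CO2 at equal rates,
dE/dt = dCO2/dt = (μ_N + β·ν_E(E)·μ_S(S))·X with Monod kinetics
μ_S = μ_S_max·S/(K_S + S) and hyperbolic ethanol inhibition
ν_E = 1/(1 + E/K_E), and consumes sugar stoichiometrically,
dS/dt = −k·dCO2/dt. The inhibition is written 1/(1 + E/K_E) so that K_E is
a concentration (g/L); the shipped values (36–73 g/L) then give a
half-inhibition at wine-scale ethanol levels. E and CO2 are integrated as
separate states although their derivatives coincide, so restarts with
E(0) ≠ CO2(0) stay well-posed; E ≡ CO2 from a zero start is verified in
the suite.

Units are fixed package-wide: g/L for concentrations, hours for time.

## Yield families

The endpoint identity X(∞) − X(0) = ∫₀^{N(0)} y(n) dn = f(N(0)) makes the
cumulative yield curve f (with f(0) = 0, y = f′) directly fittable from
endpoint data. Two closed-form families are provided:

* **linear_smoothed** — f linear (slope a, intercept b) above a threshold
  N†, joined to the origin below N† by a cubic so that f is C² and
  y = f′ is C¹: y = a + 3b(N† − N)²/N†³ below, y = a above. Constant
  maintenance α = 3b/(a(3b + aN†)) above the threshold.
* **quad_exp** — f quadratic (f = bN − aN²) below N†, continued above by
  the unique C¹ antiderivative of y = A·e^{−BN} with
  A = (b − 2aN†)e^{BN†}, B = 2a/(b − 2aN†); requires b − 2aN† > 0 for a
  positive yield, enforced at construction. Maintenance grows steeply with
  N in this family.
* **constant** — the maintenance-free limit y ≡ Y, α ≡ 0, used as the
  null model in the maintenance diagnostic.

α is always computed as 1/y(N) − 1/y(0) from the family's closed-form y;
the printed per-branch α expressions are asserted in tests rather than
implemented separately. `yield_from_maintenance` inverts the construction
(y = Y/(1 + αY)) for user-supplied α, with f by quadrature.

The `experimental-2022` preset uses the quad_exp family with stand-in
parameter values (a = 10.0, b = 13.0, N† = 0.35 g/L, flagged synthetic in
the preset metadata): they were chosen to give a plausible endpoint curve
(ΔX ≈ 4.2 g/L at N(0) = 0.567) between the two synthetic presets, since no
numeric values for the experimentally fitted yield were available — only
its functional form.

## Numerical integration

`solve_ivp` with LSODA (adaptive step, automatic stiff switching; the
system stiffens near nitrogen exhaustion), rtol = 1e-8, atol = 1e-10 by
default — tight enough that the formulation-equivalence and mass-balance
checks have headroom. State variables are clipped at zero inside the rate
laws to keep integrator undershoot from feeding back, and reported
chronicles are clipped at zero. The Contois 0/0 corner (N = X = 0) is
defined as zero rate. The reported CO2 production rate is evaluated
exactly from the right-hand side at each output time rather than by
differencing. Output grid: 1 h spacing over a 350 h horizon by default
(matching the standard operating conditions X(0) = 0.02 g/L,
S(0) = 200 g/L, N(0) ∈ [0.071, 0.57] g/L as the scenario variable).

Formulation equivalence is measured as max|Δ| over the grid divided by the
variable's trajectory maximum: a pointwise relative difference is
ill-posed where N → 0 (values ~1e-18 near exhaustion).

## Calibration

All nonlinear fits use `scipy.optimize.least_squares`
(Levenberg–Marquardt, finite-difference Jacobians) on log-parameters, so
positivity holds by construction; tolerances 1e-10 (1e-8 for noisy-data
experiments), max 2000–4000 residual evaluations, convergence reported in
every `FitResult`.

**Growth (stage 1).** dlogX/dt is estimated by central differences at
interior grid points (one-sided at the ends) and paired with r = N/X. The
nls route fits μ(r) = μ_N_max·r/(K_N + r) directly. The linearized route
regresses 1/rate on 1/r (intercept 1/μ_N_max, slope K_N/μ_N_max); the
reciprocal transform is singular at rate → 0, so this regression is
restricted to points with rate above 1e-3 of the peak rate — the
post-exhaustion points (r ≈ 0, rate ≈ 0) carry no kinetic information but
acquire unbounded leverage after inversion. The linearized route is
provided for inspection; it is systematically less reliable under
heteroscedastic noise (asserted on average over seeds in the suite).

**Yield (stage 2).** Ordinary least squares: ΔX on N0 (slope a, intercept
b) over endpoints above N† for linear_smoothed; origin-constrained ΔX on
(N0, N0²) below N† for quad_exp; through-origin regression for constant.
Weights are supported and duplication-consistent. RSE is reported with
denominator n − p. N† is not identifiable from endpoints above it; it can
be fixed, or grid-searched (`N_dagger="auto"`, default 21 candidates
spanning the N0 range) minimizing the summed normalized RMSE of the X and
N trajectories against reference chronicles — growth-step trajectories do
not depend on the sugar-step parameters, so the search needs only the
growth parameters.

**Sugar pathway (stage 3).** β, μ_S_max, K_S, K_E are fitted on CO2 and
dCO2/dt chronicles with growth and yield frozen and k = 2.17 g/g fixed
from the literature. Each variable is normalized by its maximum over the
whole dataset (not per chronicle), so all points carry equal weight.
β and μ_S_max enter the CO2 balance only through their product — an exact
structural non-identifiability. The optimizer therefore runs over the
identifiable set (β·μ_S_max, K_S, K_E), and the product is split between β
and μ_S_max symmetrically in log space around the initial guess: the
reported pair is the representative closest to the starting (literature)
values. Unconstrained fitting would instead drift arbitrarily along this
gauge direction while fitting the data perfectly.

**Simultaneous fit.** When nitrogen is never measured, all six kinetic
parameters are fitted at once on normalized CO2 (and optionally the sparse
biomass points, `use_biomass`), after the yield function has been
calibrated on endpoints and frozen; k stays fixed. The default objective
is CO2-only, mirroring how such data are usually fitted; the biomass
points sharpen the growth parameters when included.

**Metrics.** Per-variable RMSE (denominator n) after interpolating the
simulated series onto the observed times, on data divided by the observed
maximum when normalized.

## Synthetic data

The generator simulates the model itself under the standard operating
conditions and applies mean-one multiplicative lognormal noise
(σ² = log(1 + CV²)) — concentrations are positive, so additive Gaussian
noise would be the wrong support. The experimental-like design subsamples
biomass to 8 log-spaced points over [5, 350] h while keeping CO2 and its
rate dense (hourly), mimicking typical fermentor instrumentation. Noise is
applied to observations only; every dataset carries a truth record with
the exact generating parameters, the seed, and an explicit surrogate note:
the datasets emulate the *outputs* of the transporter-style and
logistic-style literature models via the correspondingly calibrated
maintenance presets — those models themselves are not reimplemented.
Endpoint datasets use the closed-form f(N0) directly (exact at zero
noise), which the simulator's endpoint identity matches to < 1e-3.

What passing the recovery tests shows: the staged procedure is consistent
and well-conditioned on data generated by the model family itself. What it
does not show: robustness to structural mismatch (real fermentations have
lag phases, temperature drift, transporter dynamics and non-Markovian
effects that the generator deliberately omits).

## Known limitations

* Isothermal only; no temperature dependence of the kinetic constants.
* No nitrogen addition (fed-batch) scenarios, though the Markovian
  structure permits them.
* No lag/latency term at inoculation.
* β and μ_S_max are reported under the gauge convention above; only their
  product is data-identified.
* Problem sizes in the test suite (3 chronicles per fit, 10 noise seeds,
  hourly grids) were chosen as the smallest designs on which every
  identifiability property is exercised.
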