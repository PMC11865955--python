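# Methods

This note records the model equations as implemented, the numerical choices,
the synthetic-data design, and the limits of what the test suite
demonstrates.

## Large-vessel model

State per vessel is (A, q)(x, t) in CGS units. Mass and momentum:

    A_t + q_x = 0
    q_t + (q²/A)_x + (A/ρ) p_x = −(2πνR/δ)(q/A),   R = √(A/π)

with the Stokes-layer friction derived from a flat velocity core and a
linear boundary layer of thickness δ = √(νT/2π). The elastic wall law

    p(x,t) − p0 = (4/3) f(x) (1 − √(A₀/A)),   f = Eh/r₀ = k₁ e^{k₂ r₀} + k₃

is evaluated with the tabulated negative k₂ (the stiffness decays with
radius toward the offset k₃). The unstressed radius r₀(x) tapers
exponentially between the measured end radii, r₀(x) = r_in (r_out/r_in)^{x/L}
(smooth, positive, matches both measurements; a linear taper is a config
alternative). Linearizing the wall law at A₀ gives the pulse-wave velocity
c₀ = √(2f/(3ρ)) and the general wave speed c(A) = c₀ (A₀/A)^{1/4}.

Density ρ = 1.06 g/cm³, dynamic viscosity μ = 0.032 g/(cm s) and kinematic
viscosity ν = 0.030 cm²/s are stored as tabulated; ν is a rounded μ/ρ, and
everywhere viscosity enters the impedance model it enters as ρν so that the
analytic ω = 0 (Poiseuille) branch is continuous with the ω > 0
transmission-line evaluation. Pressures are computed relative to the
reference p0 (default 0) and reported in mmHg (1 mmHg = 1333.22 g/(cm s²)).

## Numerical scheme

Conservation form with flux F = (q, q²/A + B), B = (4/(3ρ)) f √(A₀A), and a
momentum source collecting friction plus the geometric terms produced by the
x-dependence of f and A₀ (the source exactly balances ∂B/∂x at A = A₀, so a
vessel at rest is an equilibrium). Interior points advance with the two-step
Richtmyer Lax–Wendroff scheme (half-step at cell faces, full step from face
fluxes); the A-update telescopes, so interior mass is conserved to round-off.
Verified second-order convergence (measured slope ≥ 1.8 on a smooth
frictionless pulse).

Boundary points are closed by outgoing Riemann-invariant extrapolation.
The invariants of this wall law are W± = u ∓ 4c carried at speeds u ± c; for
tapered, frictional vessels they are not constant along characteristics, and
the closure integrates their source

    dW±/dt = φ_fric − p_x^e/ρ ∓ 4 c_x^e (u ± c)

(φ_fric the friction acceleration, superscript e the explicit x-derivatives
at fixed A) over the extrapolation step. Omitting this term biases the mean
flow by O(1%) per tapered vessel; with it the network-wide periodic mass
balance closes to ~0.1%.

Physical closures at t^{n+1}: prescribed inflow q(0,t) at the root (area from
W−, scalar Newton); at junctions q_p = q_d1 + q_d2 and p_p = p_d1 = p_d2
solved by Newton in the three areas with velocities slaved to the outgoing
invariants (residuals below 1e−10 in scaled units: flow relative to the local
flow scale, pressure relative to (4/3)f); at terminals the convolution
closure p − p0 = z ⊛ q with the current-cycle flow history (scalar Newton).
A vessel split into two via a single-child junction reproduces the unsplit
vessel to ~1e−4 of the pulse amplitude.

Time step: n_t steps per cycle, chosen from the CFL bound with a 1.5× speed
margin (so ±30% stiffness excursions during inference never trip it) unless
fixed explicitly; a runtime CFL violation doubles n_t and restarts. Grid:
`points_per_cm` (default 1) with ≥ 5 points/vessel. Cycles iterate from a
resistor-network steady state (mean flow distributed by downstream DC
resistances, areas from the inverted wall law) until the relative L2 change
of the pressure field between cycles falls below `periodicity_tol` (default
1e−3; the transient decays ≈ 2× per cycle, so 1e−4 costs ~3 extra cycles).
For calibration the cycle count is frozen at the nominal-parameter value +1
so the objective is a smooth deterministic function of the parameters.

## Structured-tree outflow

Daughter radii α·r and β·r (nominal 0.9/0.6), vessel length ℓrr·r (nominal
50), truncation below r_min (0.001 cm arteriolar, 0.01 cm for the descending
aorta). A branch whose radius falls below r_min is not generated; a vessel
with no surviving daughters carries zero terminal load; with one surviving
daughter the junction reduces to that daughter. Small-vessel stiffness uses
the same exponential law with (ks₁, ks₂, ks₃).

Per vessel, the linearized periodic flow equations give the transmission
line with Womersley factor F_J = 2J₁(w₀)/(w₀J₀(w₀)), w₀² = i³r₀²ω/ν,
compliance C = 3A₀/(2f), g = √(CA₀(1−F_J)/ρ), c = √(A₀(1−F_J)/(ρC)). Since
radii depend only on the (α-step, β-step) counts, the recursion is memoized
on that lattice (O(depth²) nodes instead of 2^depth). Numerical handling of
1−F_J: a direct series below |w₀| = 0.1 (1 minus the Bessel ratio cancels
catastrophically there), the J₁/J₀ → i asymptote where J would overflow, and
in between a dense log-spaced cubic spline in the single real variable
r₀√(ω/ν) (1−F_J is smooth along the e^{3πi/4} ray; interpolation error
≤ ~2e−6 relative, built once per process). The DC value is the series/
parallel Poiseuille resistance, verified against an independent brute-force
resistor-network recursion to 1e−8.

The root spectrum at harmonics 2πk/T, k = 0..n_t/2, becomes a real cyclic
kernel by conjugate-symmetric inverse DFT (Nyquist bin symmetrized to its
real part); the solver convolves it with the rolling outlet-flow history.

## Post-processing

Wave intensity uses per-step increments dp± = ½(dp ± ρc du), du± = ½(du ±
dp/(ρc)) with c the local linearized pulse-wave velocity at the analysis
point (a PU-loop estimate can be supplied instead); the decomposition and
reconstruction identities are exact by construction. Compressive wave
amplitude Δp± is the largest contiguous rise of the cumulated component over
runs of positive increments; I_R = Δp₋/Δp₊, NaN when no incident compressive
wave exists. Wall shear stress is τ_w = μ(q/A)/δ with dynamic μ (a stress
requires dynamic, not kinematic, viscosity).

## Sensitivity, identifiability, inference

All analyses work on named parameter dictionaries with log-magnitude scaling
θ = sign·e^{θ̃}, which keeps relative perturbations meaningful for the
negative decay rates k₂, ks₂ as well. Local: centred differences with step
ψ = 0.01, ranked by column 2-norm; one-sided fallback (logged) if a
perturbed forward solve fails. Morris: K samples (100 nominal, fewer at desk
scale) of one-at-a-time elementary effects on an M = 60-level grid with step
Δ = M/(2(M−1)) ≈ 0.508 in unit-hypercube coordinates over ±10% (stiffness)
and ±5% (tree geometry) ranges; per-sample effect-vector 2-norms summarized
by μ* (mean magnitude) and σ² (sample variance), ranked by μ*² + σ²,
tie-broken by μ*; deterministic per seed; failed trajectories resampled.
Covariance: V = s²(SᵀS)⁻¹ (pseudo-inverse with a structural flag when
singular), pairs with |correlation| > 0.9 flagged. Subset selection: drop
parameters below 5% of the top local/Morris statistic, then fix the
lower-ranked member of each flagged pair (combined local+Morris rank),
with an audit log.

The calibration residual stacks four flow blocks (q_model − q_data)/max(q_data)
at the data's Tp cycle times (model flows evaluated by trigonometric
interpolation of the converged cycle) and two relative cuff residuals
(model systolic/diastolic = max/min pressure at the cuff vessel's midpoint).
The RSS is minimized by SLSQP (an SQP method) with tolerance 1e−8, bounds in
natural scale (default ×/÷2 of nominal; tree α capped at 0.99), and forward
finite-difference gradients with step 1e−4 on the log coordinates (SA's ψ is
separate). Multistart: 12 starts uniform within ±30% of nominal. The final
cost of every start is recorded and convergence across optimizations is
checked first: starts whose final RSS exceeds the best by more than 10%
(plus an absolute floor at the finite-difference noise level) sit in
inferior local optima and are excluded, since they measure landscape
multimodality rather than dispersion of the estimate. CV = sd/mean of each
parameter's estimates over the converged starts; if any CV exceeds 0.1, the
offending per-group family is collapsed to one global value (pooled
nominal), or removed if already global, and the loop repeats (≤ 4 rounds);
the reported estimate is the minimum-RSS start. Model and data are
cycle-aligned by construction (shared inflow origin), so no foot alignment
is applied to synthetic data.

## Synthetic patients

The generator defines the study conditions: cohort-mean geometry with
multiplicative lognormal jitter (σ = 0.05; one radius factor per vessel so
each vessel's taper direction — e.g. the widening reconstructed ascending
aorta — is preserved by construction), truth parameters at the cohort
nominal values, cycle length from the cohort mean ± sd truncated to the
measured range, cardiac output uniform in the cohort's measured range, and a
half-sine systolic ejection inflow (35% systolic fraction ± small jitter, 2%
diastolic baseline) sampled at Tp ∈ [19, 28] points. Measurements: five
replicates per site with 5% multiplicative Gaussian noise, per-branch
de-conservation factors of magnitude 5–15% (random sign), and cuff values
from the truth pressure extrema ± 1 mmHg Gaussian offset. Generation is
bit-reproducible per seed; failed jittered geometries are re-drawn (≤ 5
attempts).

What the generator does not emulate: imaging artefacts, registration error,
spatially correlated velocity noise, beat-to-beat variability, or model
discrepancy — the synthetic data come from the same model family that is
fitted (deliberately: the tests measure the pipeline, not model adequacy).
Recovery results on synthetic twins therefore bound what real data could
show from above.

A note on pressure scale: at the tabulated nominal parameters the structured
trees carry a total DC resistance of ≈ 680 CGS for the canonical network, so
mean aortic pressure at 4 l/min is ≈ 34 mmHg — below cuff-normal. The DC
resistance depends only on tree geometry and viscosity, not on the stiffness
parameters; the synthetic cuff values are therefore the model's own (fully
self-consistent for calibration), not values in the clinically measured
range.

## Desk-scale problem sizes

The identifiability study runs on a reduced 3-vessel subnetwork (ascending
aorta → descending aorta + innominate, both daughters terminal), grid
0.25 points/cm with ≥ 5 points/vessel, Tp = 20, four calibration sites (two
per daughter vessel), subset {tree_alpha, k3_1, ks2, ks3_1, ks3_2}. The
Morris sample count in examples is reduced to stay interactive. All
statistic definitions, thresholds (CV 0.1, correlation 0.9, R² 0.8) and the
12-start protocol are unchanged from the full-scale settings.

## Known limitations

- No junction energy-loss terms: pressure is continuous across bifurcations,
  which overestimates transmission for the abnormal HLHS arch geometries.
- The characteristic boundary closure is locally first-order in the
  source-term integration; the residual single-junction reflection is
  ~1e−4 of the pulse amplitude and the network mass imbalance ~0.1%.
- The tree terminal load is identically zero: no venous back-pressure or
  vasoregulation.
- The calibration objective ignores the temporal correlation of measurement
  errors (plain least squares).
- Parameter bounds, ψ, and the FD gradient step are package defaults where
  the protocol leaves them open.
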