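# Methods

## Model

The package implements a single-mode thixotropic elasto-visco-plastic
(TEVP) constitutive law for whole blood.  The state of a material point is
the symmetric viscoelastic stress tensor τ (Pa) and a scalar structure
parameter λ ∈ [0, 1] measuring the instantaneous degree of rouleaux
aggregation.  The model combines four ingredients:

1. **Elasto-viscoplastic decomposition.**  The total deformation rate
   splits additively, D = D_e + D_vp, with the elastic part defined through
   the upper-convected stress rate, D_e = (1/2G) τ^∇.  For the homogeneous
   rheometric flows simulated here the advection term of τ^∇ vanishes and
   the stress evolution is dτ/dt = L^T·τ + τ·L + 2G (D − D_vp), with the
   velocity-gradient convention L_ij = ∂u_j/∂x_i (simple shear
   u = (γ̇ y, 0, 0) puts γ̇ in L[1,0], making τ_xy the shear stress and
   τ_xx the elastically generated normal stress; the model then predicts
   τ_yy = τ_zz ≡ 0 in shear, which is a test, not an assumption — the full
   3-D symmetric tensor is always carried).
2. **Von Mises yielding.**  Plastic flow is proportional to the stress and
   switches on continuously at the yield surface:
   D_vp = f[tr τ]·max(0, (σ_eff − τ_y)/(2 η_t σ_eff))·τ with
   σ_eff = sqrt((τ_D:τ_D)/2).  The scalar multiplier is evaluated with the
   max() clamped before the quotient, so σ_eff = 0 never produces 0/0.
3. **Linear PTT mobility.**  f = 1 + ε_PTT tr(τ)/G bounds the extensional
   viscosity at strong elongation rates; with ε_PTT = 0 and τ_y = 0 the
   model reduces exactly to an upper-convected Maxwell fluid with
   relaxation time χ₀ = η₀/G (this limit anchors the integrator tests).
4. **Structure kinetics.**  dλ/dt = (k₁ + k₂ φ^n1)(1 − λ) − k₃ φ^n3 λ^n2,
   with the stress-controlled driving force φ = max(0, σ_eff − τ_y).
   Rebuild has a Brownian floor k₁ active even at rest; breakdown is
   proportional to a power of the structured fraction.  The λ-exponent of
   the breakdown term is n2 and its stress exponent n3; for the bundled
   blood sets n3 = n1, so the strong-flow balance k₂(1 − λ) = k₃ λ^n2 is
   stress-independent and λ saturates at λ∞ (0.177 and 0.087 for the two
   presets).  This pairing of exponents is what gives the model its
   physiologically essential high-shear behaviour — a finite residual
   structure and a high-shear viscosity plateau of 3–4× the plasma
   viscosity (η₀ λ∞^m1 ≈ 3.5 mPa·s for the default set) with relaxation
   time χ∞ ≈ 9 ms — and it is the pairing consistent with the published
   characterization of these parameter sets (steady structure sigmoid,
   viscosity plateau, cessation and step-test structure traces).

Kinematic and isotropic hardening are deliberately absent: the yield
stress is history-independent, and τ_eff = τ_ve.  Thixotropy is single-mode
(one structural time scale), which keeps the model cheap enough for
multi-dimensional flow solvers.

### Parameters

| symbol | field | units | default (subject preset) | role |
|---|---|---|---|---|
| G | `G` | Pa | 0.382 | elastic modulus |
| η₀ | `eta0` | Pa·s | 0.012 | structural viscosity at λ = 1 |
| τ_y | `tau_y` | Pa | 0.0035 | yield stress |
| ε_PTT | `eps_ptt` | – | 0.001 | extensional mobility |
| k₁ | `k1` | 1/s | 0.0918 | Brownian rebuild rate |
| k₂ | `k2` | (rate) | 7.249 | flow-induced rebuild coefficient |
| k₃ | `k3` | (rate) | 6974.9 | breakdown coefficient |
| n1, n2, n3 | | – | 3.03, 4.068, 3.03 | kinetic exponents (see above) |
| m1 | `m1` | – | 0.701 | viscosity–structure exponent |

χ₀ = η₀/G is derived (31.4 ms for the default set).  Physical sets require
k₃ ≫ k₂ and n1 < n2 (warned, not rejected).  τ_y, k₂, k₃ may be zero —
degenerate Maxwell-type limits used for verification — while G, η₀, k₁ and
all exponents must be positive.  Units are strict SI internally; mPa
conversions happen only in reporting layers.

## Numerics

**Integrator.**  The seven-variable ODE system is advanced by a
second-order predictor–corrector with adaptive step: a variable-step
Adams–Bashforth-2 predictor (plain Euler on the first step after an event)
and an A-stable trapezoidal corrector solved by modified Newton with a
finite-difference Jacobian.  Steps are accepted when the scaled
predictor–corrector discrepancy is below one (rtol 1e−6, atol 1e−9 by
default); rejection halves the step and clears the multistep history.
Protocol discontinuities (startup, cessation, step edges) are exact event
times at which integration restarts with the state carried over — the step
is never smoothed.  λ excursions outside [0, 1] beyond 1e−6 reject the
step; residual round-off is clipped.  A fixed-step mode exists solely for
order verification (the suite checks the error falls ≈ 4× per step
halving).  An η_t floor of 1e−12 Pa·s protects the plastic multiplier;
since the kinetics keep λ > 0 it is never active in practice.

**Steady states.**  Constant-rate runs are marched until the mean state
change per second over a trailing horizon falls below `steady_tol`
(1e−6/s); judging steadiness on a horizon average rather than the
instantaneous right-hand side makes the detector immune to step-level
integration wobble.  The marched state then seeds a Newton solve of the
algebraic system (scipy hybr), accepted only if it stays within 1e−4 of
the marched state — a guard against the root-finder sliding across the
yield-surface kink.  Steady *shear* sweeps use an exact reduction: at
steady state τ_yy = τ_zz = 0 and τ_xx = 2 τ_xy²/G, leaving a 2×2 root
problem in (log τ_xy, λ) swept by continuation from high rate to low
(low-rate states are stiff near the yield point).  The time-marched and
algebraic routes are cross-checked against each other in the tests.

**Oscillatory states.**  LAOS runs integrate cycle by cycle until the
relative L2 distance between consecutive cycles' (τ_xy, λ) traces on a
common phase grid falls below `cycle_tol` (1e−5); hitting the cycle cap
returns the last cycle flagged non-periodic.

**Derived metrics.**  The startup steady value τ_st is the mean over the
trailing 1% of the converged window; the overshoot peak is refined by
parabolic interpolation and the half-decay time θ by monotone (PCHIP)
interpolation of the post-peak decay.  An overshoot is declared only above
a 0.1% relative excess, so round-off ripples never produce spurious
thixotropic indices.  The maximum of the thixotropic index
ξ = (τ_max − τ_st)/(τ_st θ γ̇) is located by a log-spaced sweep at 8
points per decade over 0.1–1000 1/s followed by golden-section refinement;
ξ(γ̇) is smooth and unimodal for blood-like sets, so this resolves the
maximum well below the comparison tolerances at a fraction of the cost of
a dense grid.  The structure-breakdown onset in extension is defined as
the first 1% drop of λ.  The Morris yield-stress correlation is evaluated
in its native dyn/cm² and converted (1 dyn/cm² = 0.1 Pa); its inversion
takes the smaller root of the fibrinogen quadratic, which is the unique
root inside the correlation's validity rectangle (Hc 0.40–0.80, c_f
0.1–0.9 g/dL; outside, the functions warn).

**Fits.**  The sigmoid λ_s(γ̇) and rational N1(ε̇) descriptions are
nonlinear least squares (scipy) with linearised initial guesses; the
generalized-Newtonian comparators (Casson, Cross, Carreau–Yasuda in their
standard literature forms) are fitted on log-viscosity with log-space
positivity parameterisation.

## Calibration and synthetic data

The calibration objective concatenates log-space steady residuals (the
flow curve spans decades) with linear transient residuals normalised per
block by the block's own RMS, so steady and transient data contribute
comparably — the weighting is this package's choice, as is the multi-start
strategy: bounded trust-region least squares over log-parameters with
eight log-uniform starts by default, deterministic per seed.  Failed
simulations at trial points return a large finite penalty rather than
raising.  Small-amplitude oscillatory data can be attached to a dataset
but is not part of the default objective.

The synthetic-data generator simulates exact model curves for a
measurement design and applies multiplicative log-normal noise of a given
coefficient of variation (mean-preserving; cv = 0.02 by default).  The
default design mirrors the protocols behind the bundled subject preset —
a steady sweep over 0.01–1000 1/s (24 log-spaced points) and an
intermittent trace (7 1/s, 2.5 s pulses, 1.5 s rest) — plus a triangular
ramp (a = 10 1/s², t_max = 6 s) of the kind used for the second donor.

**What passing recovery tests show — and what they do not.**  The
generator reproduces the noise structure (multiplicative, independent) but
not rheometer artifacts: no inertia or gap-loading transients, no
cone-and-plate inhomogeneity at high rates, no sample ageing or
sedimentation, no temperature drift.  Parameter recovery on synthetic data
therefore demonstrates identifiability of the eleven constants under the
model's own assumptions, not robustness to instrument systematics.  The
kinetic constants are the weakly identified directions — consistent with
the orders-of-magnitude spread between the two bundled donors' k values —
which is why recovery is exercised at zero noise from ±30% perturbed
starts rather than asserted tightly under noise.

## Known limitations

- Homogeneous kinematics only: the imposed L(t) is uniform, so rheometer
  flows are treated as ideal; no momentum balance, no inertia, no wall
  slip.
- Several published checkpoint values for the fitted subject are mutually
  inconsistent (the triangular-ramp stress peaks against their own
  structure traces; the steady viscoplastic split at 350 1/s against the
  stated viscosity plateau; the uniaxial-extension section against the
  shear-fitted kinetics — the extensional yield plateau of this model is
  necessarily √3 τ_y ≈ 6.1 mPa).  The implementation follows the
  self-consistent majority of the characterization — the steady structure
  sigmoid, viscosity and relaxation-time plateaus, cessation and
  intermittent traces — and the remaining checkpoints fail honestly in
  `tests/test_acceptance.py` at their stated tolerances.
- The "memory-loss" claim that rest intervals beyond 1/k₁ ≈ 11 s have no
  further effect on the second pulse holds only asymptotically: with
  exponential rebuild, peaks for Δt ∈ [12, 22] s still spread by ≈ 5%.
- Single structural time scale and scalar λ: no distinction between linear
  rouleaux and 3-D networks, no aggregate-size distribution, no
  hematocrit/temperature dependence of the constants (composition enters
  only through the Morris yield-stress correlation).
- Stress-controlled kinetics: rate-controlled variants (a different
  constitutive assumption) are not implemented.
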