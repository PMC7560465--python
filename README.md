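# hemotevp

Thixotropic elasto-visco-plastic (TEVP) constitutive modelling of whole
blood: a tensorial single-mode model of the coupled viscoelastic stress and
rouleaux microstructure, simulators for the standard rheometric protocols,
derived rheometric metrics, and a calibration engine for the model's eleven
constants.

**Who it is for.** Hemorheologists and computational biomechanics groups who
need a transient, tensorial blood model — one that captures yield stress,
elasticity and thixotropy simultaneously — for interpreting rheometer data
(startup, cessation, intermittent and triangular shear steps, LAOS, uniaxial
extension) or as the constitutive core of flow simulations, and who want to
fit its parameters to their own donors' rheograms.

## The model

Blood is a suspension of red blood cells whose aggregates (rouleaux) form
and break under flow.  The extra stress is purely viscoelastic, τ = τ_ve
(the plasma solvent is folded in), and the total deformation rate splits
into elastic and viscoplastic parts, D = D_e + D_vp, with

```
D_e  = (1/2G) τ^∇                                  (upper-convected rate)
D_vp = f[tr τ] · max(0, (σ_eff − τ_y) / (2 η_t σ_eff)) · τ
f[tr τ] = 1 + ε_PTT tr(τ)/G                        (linear PTT factor)
σ_eff = sqrt((τ_D : τ_D)/2)                        (von Mises effective stress)
```

so the material is neo-Hookean below the yield surface (σ_eff ≤ τ_y) and
flows plastically above it.  A scalar structure parameter λ ∈ [0, 1]
(λ = 1: fully structured rouleaux network; λ → 0: dispersed cells) carries
the thixotropy through the structural viscosity and relaxation time

```
η_t(λ) = η₀ λ^m1 ,   χ(λ) = χ₀ λ^m1 ,   χ₀ = η₀/G
```

and evolves by stress-driven kinetics with driving force
φ = max(0, σ_eff − τ_y):

```
dλ/dt = (k₁ + k₂ φ^n1)(1 − λ)  −  k₃ φ^n3 λ^n2
```

Brownian collisions (k₁) and flow (k₂) rebuild the structure in proportion
to the unstructured fraction; flow breaks it down in proportion to a power
of the structured fraction.  Because the stress exponents of rebuild and
breakdown are equal for the fitted blood sets (n1 = n3), the strong-flow
balance k₂(1 − λ) = k₃ λ^n2 pins λ at a finite plateau λ∞ ≈ 0.18: blood
never becomes fully unstructured, and the high-shear viscosity settles at
3–4× the plasma viscosity.  See `docs/methods.md` for assumptions,
numerics, and known limitations.

Two fitted parameter sets are bundled (`mcmillan1987_subject`, the default,
and `armstrong2018_donor1`); the Morris hematocrit–fibrinogen correlation
links the yield stress to blood composition.

## Worked example

```python
import numpy as np
import hemotevp as h

p = h.load_preset("mcmillan1987_subject")

# startup + cessation at 14.1 1/s, flow switched off at t = 3 s
r = h.integrate(h.ProtocolSpec.cessation(14.1, 3.0, t_end=40.0), p)
print(f"overshoot peak : {1e3 * r.txy.max():.1f} mPa "
      f"at t = {r.t[r.txy.idxmax()]:.3f} s")
print(f"structure at cessation : lam = {np.interp(3.0, r.t, r.lam):.3f}")
print(f"residual stress : {1e3 * r.txy.iloc[-1]:.2f} mPa "
      f"(yield stress {1e3 * p.tau_y:.1f} mPa)")

# steady flow curve
fc = h.flow_curve(p, np.geomspace(0.01, 1000.0, 5))
print(fc[["rate", "txy", "lam", "eta_app"]].round(5).to_string(index=False))
```

prints

```
overshoot peak : 136.2 mPa at t = 0.068 s
structure at cessation : lam = 0.361
residual stress : 3.39 mPa (yield stress 3.5 mPa)
      rate     txy     lam  eta_app
   0.01000 0.00362 1.00000  0.36198
   0.17783 0.00563 0.99939  0.03167
   3.16228 0.03222 0.67270  0.01019
  56.23413 0.22120 0.20008  0.00393
1000.00000 3.13227 0.17618  0.00313
```

The elastic loading produces the stress overshoot a fraction of a second
into the shearing; breaking rouleaux then relax the stress toward its
steady value.  When the flow stops, the stress falls to — and is arrested
at — the yield surface (≈ 3.5 mPa), while λ rebuilds at the Brownian rate
k₁.  The flow curve shows the yield-stress plateau at vanishing rate, shear
thinning through the rouleaux transition, and the high-shear viscosity
plateau of about 3.5 mPa·s.

A command-line interface mirrors the library:

```
hemotevp simulate --protocol cessation --rate 14.1 --t-ces 3 --out r.csv
hemotevp flowcurve --out fc.csv
hemotevp synth --seed 3 --out data.csv && hemotevp fit data.csv
hemotevp report          # recompute the preset's published characterization
```

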