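# Methods

`pulsead` is a reduced-order (0D + quasi-1D) model of compliant
haemodynamics in a type-B aortic dissection: a branched arterial network
with three-element Windkessel (WK3) outlets, a pressure–area wall law
derived from a nodal moving-boundary formulation, a patient-specific
tuning procedure for all boundary parameters, and the clinical
post-processing indices used to characterize dissection haemodynamics.
This note records the model equations, the numerical choices, the
synthetic data conditions, and the limits of what the desk-scale fixture
can and cannot show.

## Lumped (0D) elements

Each outlet is a WK3 with proximal resistance R1, distal resistance R2
and compliance C, relating boundary flow and mean pressure by

    P + R2·C·dP/dt = (R1 + R2)·Q + R1·R2·C·dQ/dt.

Vessel segments of the 0D tuning network are inertance–resistance blocks
with the standard tube identities L = ρℓ/A0 and R = 8πμℓ/A0²
(Poiseuille). All 0D interfaces use clinical units (mmHg, ml/s, ml/mmHg);
the single conversion constant 1 mmHg = 133.322 Pa lives in
`pulsead.units`.

Both elements are discretized with first-order backward Euler at a 1 ms
step. An assembled network is solved fully implicitly: the backward-Euler
element relations are linear in the unknown junction pressures, so each
step is one LU back-substitution of a small constant matrix. The solver
runs whole cardiac cycles until the cycle-to-cycle maximum relative
pressure change drops below 0.5% (default cap 20 cycles); pressures
initialize at the diastolic target with zero flows.

## Wall law (moving boundary, axisymmetric embodiment)

The wall model displaces each node along its outward normal in linear
proportion to the local transmural pressure, δ = (p − p_ext)/K, with
stiffness tied to the area compliance of a circular cross-section,
K = 2√(πA0)/C_A. Embodied axisymmetrically (the normal is the radial
direction), composing δ with A = π(r0 + δ)² yields the tube law

    p = p_ext + β(√A − √A0),    β = 2√A0 / C_A,

whose linearization at p_ext is exactly C_A and whose reference wave
speed is the Bramwell–Hill speed c0 = √(A0/(ρ C_A)) = 1/√(ρD) with
distensibility D = C_A/A0. The external pressure p_ext defaults to
76 mmHg (the mean diastolic pressure over the wall in the clinical
dataset). The full 3D mesh-motion solve is out of scope; the axisymmetric
reduction preserves the constitutive content (linear δ–p through K) at
desk scale.

## Quasi-1D solver

Cross-sectionally averaged mass and momentum,

    ∂A/∂t + ∂Q/∂x = 0
    ∂Q/∂t + ∂(Q²/A + B)/∂x = f + S_geom,  B = βA^{3/2}/(3ρ),

are integrated with the two-step Richtmyer Lax–Wendroff scheme
(second-order in the interior). `S_geom` carries the property-gradient
terms (β′, A0′) so tapered segments remain consistent; uniform fixture
segments have S_geom = 0. Friction assumes a Poiseuille profile,
f = −8πμ(γ̇_w)Q/(ρA), with the Carreau–Yasuda apparent viscosity at the
wall shear rate (defaults μ0 = 22, μ∞ = 2.2 mPa·s, λ = 0.110 s,
a = 0.644, n = 0.392 — literature values for aortic blood; ρ = 1056
kg/m³). The momentum-flux coefficient is 1: at the aortic Womersley
number (~23) the velocity profile is nearly flat and profile detail is
secondary.

Boundaries and junctions couple through the Riemann invariants
W₁,₂ = u ± 4c of the tube law (c ∝ A^{1/4}):

* prescribed-flow ends solve u(A)·A = Q against the incoming invariant;
* WK3 outlets solve pressure continuity p(A) = P_wk3(Q) with the
  backward-Euler Windkessel relation folded in (one scalar Newton);
* junctions impose static-pressure continuity and mass conservation,
  one scalar Newton per junction on the common pressure (a total-pressure
  variant was considered and not adopted: the static closure is the
  simplest consistent one and keeps the strong, physically expected
  reflection at the true-lumen narrowing);
* closed ends (distal false lumen) set Q = 0.

The entry tear is a quasi-steady sharp-edged orifice,
Q = sign(ΔP)·Cd·A_tear·√(2|ΔP|/ρ) with Cd = 0.6 and A_tear = 18.5 mm²,
explicitly coupled with a linearized core for |ΔP| < 50 Pa so the
√-law's infinite slope at ΔP = 0 cannot destabilize the explicit
exchange. The intimal flap is rigid and transmits no displacement; the
dissected region's combined (TL+FL) area compliance splits between the
lumina in proportion to their reference areas.

The solver sub-steps internally to the CFL limit (0.9 safety) below the
1 ms output grid, runs until the cycle-to-cycle maximum relative pressure
change is below 1%, and reports the last cycle. Per-cycle volume closure
on the fixture is ~10⁻⁵ of stroke volume; halving the grid spacing
changes outlet pressures by well under 2%.

**Rigid mode.** With A ≡ A0 the network is exactly an
inertance–resistance lumped system (an explicit hyperbolic scheme has no
rigid limit — the wave speed diverges), so the rigid flag delegates to
the implicit 0D solver built from the same geometry and expands the
solution to per-node fields. The false lumen, fed only through the tear
and distally closed, carries identically zero flow in this mode.

## Tuning procedure (4 steps)

1. **Whole-system WK3 fit.** A single WK3 driven by the aortic inflow is
   fitted to the brachial systolic/diastolic targets (150/80 mmHg):
   inner log-space bisection on C against pulse pressure, outer
   multiplicative fixed point on R_tot against P_sys + P_dia. Both
   extremes are matched to 0.05 mmHg (contract: 0.5 mmHg). The
   R1/R_tot ratio is 0.056 (configurable; the value seeds steps 1–2 only
   and step 4 overwrites R1).
2. **Distribution over outlets.** C_sys is split proportionally to
   target mean flows. Each outlet's R_tot follows the fixed point
   R_tot,i ← P̄_i/Q̄_i^target on the 0D network. Because every 0D
   boundary is a prescribed flow, the network constrains only resistance
   ratios; the level is anchored by holding the inlet mean pressure at
   the step-1 value, so each terminal's anchor is that value minus its
   measured mean series drop (with a single outlet this reduces to the
   system R_tot minus the series resistance). Convergence: achieved mean
   flows within 1% (typically 1–2 iterations). Venous reference: 0 mmHg.
3. **Compliance estimation.** A rigid run of the distributed model gives
   the local systolic–diastolic excursion ΔP at each aortic segment
   midpoint; cine-like area waveforms give the peak normalized variation
   ΔA*, and D = ΔA*_peak/ΔP. Dissected-region distensibility uses the
   combined TL+FL area. Branch distensibilities come from the empirical
   PWV–diameter law PWV = a/d^b (a = 13.3 m/s at 1 mm, b = 0.3) through
   Bramwell–Hill D = 1/(ρPWV²). C_A = D·A0 integrates along the vessels
   to the aortic compliance C_aorta. For noisy area data the package
   provides a regression estimator (OLS of A on P); the peak-based
   estimator is exact on noise-free signals but keys on extreme samples
   and inflates D under measurement noise.
4. **Impedance-matched re-tune.** Only the peripheral remainder
   C_per = C_sys − C_aorta is distributed over the outlets (budget
   closure is exact by construction); R_tot,i is kept from step 2 and
   R1,i is set to the characteristic impedance ρ·PWV_i/A0,i of the
   coupled vessel to minimize artificial reflections at the interfaces.

The pipeline then simulates the compliant model to periodic steady state
and reports achieved-vs-target flows and pressures.

## Clinical indices

* **Foot-to-foot PWV**: the wave foot is the pressure minimum
  immediately preceding the maximal upstroke slope (cyclic search,
  parabolic sub-sample refinement, ties to the earliest time);
  PWV = distance/Δt_foot.
* **ΔA%** = 100·(A − A_min)/A_min over the cycle.
* **TAWSS** = (1/T)∫|τ_w|dt and **OSI** = ½(1 − |∫τ_w dt|/∫|τ_w|dt),
  clamped to [0, 0.5]; an identically zero shear signal has OSI = 0 by
  convention.
* **TMP** = P_TL − P_FL at matched axial stations.
* **Stored volume** = ∫(Q_in − ΣQ_out)dt over the systole window
  (inflow upstroke to return-to-baseline at 1% of peak, overridable).

All index integrals use trapezoidal quadrature on the periodic closure
of the last simulated cycle.

## Synthetic study conditions

The fixture replaces the patient's imaging with generated stand-ins:

* **Inflow**: half-sine systolic ejection over one third of the cycle, a
  small backflow lobe (2% of stroke volume), zero diastolic flow;
  SV = 107.6 ml, HR = 75 bpm (cardiac output 8.1 l/min, cycle mean
  134.5 ml/s). The cycle integral is renormalized to the stroke volume
  exactly.
* **Branch flows**: damped-pulsatility copies of the inflow envelope with
  exact means (RCC 12.7, LCC 8.9 ml/s prescribed; RSA/LSA 9.8, CT 20.7,
  SMA 14.0, RRA/LRA 14.0, AbAo 30.5 ml/s as Windkessel targets).
* **Geometry**: 14 segments mirroring the clinical topology — ascending
  aorta/arch (32 mm diameter, consistent with mean Reynolds ≈ 1400 and
  Womersley ≈ 23), arch branches, a short descending segment, the
  TL (14 mm)/FL (20 mm) pair with one proximal 18.5 mm² tear and closed
  FL end, visceral branches, abdominal aorta. Dimensions are documented
  literature-typical adult values, not patient measurements.
* **Area waveforms**: A(t) = A0(1 + D(P − P_min))(1 + ε) with seeded
  multiplicative noise; regional distensibility defaults (ascending
  1.18e-5, descending 1.30e-5, abdominal 1.66e-5 Pa⁻¹) emulate the
  measured area variations (~11% ascending, ~17% abdominal).

All generators are deterministic given a seed.

## What the desk-scale model does and does not show

The fixture reproduces the study's mechanistic findings: the rigid model
admits no false-lumen flow while the compliant model drives an
oscillatory tear exchange; transmural pressure is positive through most
of systole and negative in diastole; aortic compliance attenuates
systolic and augments diastolic true-lumen flow; the stored systolic
volume closes against C_aorta × pulse pressure; foot-to-foot PWV on a
uniform tube matches Bramwell–Hill within 5%.

Quantities tied to the patient's measured waveform shape do not
transfer. The synthetic half-sine systole concentrates the stroke volume
into a 646 ml/s peak — sharper than a measured aortic ejection — which
raises the whole-system compliance that reproduces a 70 mmHg pulse
pressure (≈1.40 ml/mmHg here) and amplifies inlet systolic pressure in
the compliant run through the characteristic-impedance term z0·Q̂, so the
achieved-vs-target deviation of the tuned model (≈8%, dominated by
P_sys) exceeds the ~2% attainable with a rounder ejection waveform. Both
numbers are reported as computed; the sensitivity is a property of the
waveform shape, not of the tuning procedure, and the flow targets are met
within 1% regardless.

Also out of scope by design: 3D flow features (tear jet, vortices, WSS
maps on patient anatomy), turbulence, flap motion, image segmentation.

## Problem sizes and tolerances

Default runs use 1 ms output steps, ~150 grid nodes across 14 segments
(≥8 per segment, ~1 cm spacing), CFL-limited internal sub-steps, and
periodicity tolerances of 0.5% (0D) / 1% (1D). The full tuning pipeline
with the final compliant simulation completes in well under a minute on
one CPU; fitting tolerances are 0.05 mmHg on pressure extremes and 1% on
mean flows, all deterministic (bisection/fixed-point, no randomness).
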