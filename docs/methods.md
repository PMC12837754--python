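# Methods

## Geometric parameterization

The mitral valve is reduced to 12 parameters sampled uniformly within
physiological ranges (mm where dimensional):

| normalized | range | physical | unnormalization |
|---|---|---|---|
| AP_D | [24.1, 45.2] mm | AP | AP = AP_D |
| IC_D_R | [0.97, 1.29] | IC | IC = IC_D_R · AP |
| AL_R | [3.2, 7.2] | AL | AL = AP / AL_R |
| PL_R | [0.16, 1.0] | PL | PL = PL_R · (AP − AL) |
| CL_R | [0.5, 0.75] | CL | CL = CL_R · (PL − PH) |
| SF_Shape_R | [0.01, 0.019] | SF_shape | SF_shape = SF_Shape_R · IC |
| Ant_Blunt | [0.5, 2.05] | Ant_blunt | pass-through |
| AH | [0.3, 0.7] mm | AH | pass-through |
| PH | [1.0, 2.0] mm | PH | pass-through |
| D_Shape | [0, 0.038] | D_shape | pass-through |
| Com_Loc | [0.26, 0.6] | Com_loc | pass-through |
| Com_Cur | [0.2, 0.6] | Com_cur | pass-through |

**AL convention.** AL_R is tabulated in [3.2, 7.2]: it counts how many
anterior-leaflet lengths span the annular diameter, so AL = AP / AL_R
(≈ 3.5–14 mm). The alternative reading AL = AL_R · AP would make the
leaflet several times longer than the annulus and force
PL = PL_R · (AP − AL) < 0; it is geometrically impossible and is not
used.

**Feasibility.** Draws with PL ≤ PH (which would give CL ≤ 0) are
rejected and resampled, with the rejection count reported. Under the
default ranges min PL = 2.65 mm > max PH = 2 mm, so rejection never
fires; it exists for user-supplied ranges.

**Mid-systole profiles.** Over a commissural coordinate s ∈ [0, 1]
(annular plane z = 0, commissural axis x spanning [0, IC],
anteroposterior axis y):

* chord d(s) = AP · √(1 − (2s−1)²) · (1 − D_shape) ·
  (1 − (SF_shape/IC) · φ(s)), with φ a fixed Gaussian bump (width 0.2)
  centered at s = 0.5 — an elliptical orifice with D-shaped and septal
  flattening; d(0) = d(1) = 0;
* anterior length a(s) = AL · sin(πs)^(1/Ant_blunt), so a(0.5) = AL for
  every bluntness;
* posterior length p(s) = CL + (PL − CL) · w(s), where w is a mirrored
  cubic smoothstep: 0 at the commissures, 1 on the central belly,
  transition midpoint Com_loc, transition half-width 0.05/Com_cur
  (steeper for larger curvature).

Stations are midpoints of n equal cells of [0, 1] (default n = 400), so
station sums are midpoint-rule integrals with spacing Δx = IC/n; the
discrete ellipse area Σ d·Δx reaches π·AP·IC/4 within 0.5% at n = 400.
The five shape parameters without published constructions (bluntness,
D-shape, septal flatness, commissure location/curvature) use the
explicit stand-in formulas above; they are package conventions, not
measured anatomy.

## Closure emulator

The emulator replaces a finite-element closure simulation with a
deterministic kinematic rule (no tissue constitutive law, chordae,
papillary muscles, annular dynamics or hemodynamics). Its role is to be
a *statistically faithful* stand-in: physics-based studies of functional
regurgitation find orifice-area variability dominated by IC, PL, AL and
CL, with the remaining geometric parameters weak — the emulator is
designed to reproduce exactly that dominance structure while staying
analytically checkable.

Per station, the residual gap is

    g(s) = max(0, d(s) − λ(q) · m(s)) + leak(s)

with leaflet supply m(s) = α·ã(s) + p̃(s) and efficiency

    λ(q) = λ₀ · (AP/AP_ref)^δ_AP · (IC_ref/IC)^δ_IC · (1 − c_h (AH+PH)/h_ref).

Design choices, and why:

* **Shape-normalized supply.** ã and p̃ are the anterior/posterior
  profiles rescaled so their station-integrals are fixed fractions of
  the length budget (a_ref = 2/π for the anterior shape, w_ref = 0.80
  for the posterior ramp). Bluntness and commissure-shape parameters
  then *redistribute* coaptation tissue along the free edge without
  changing the total, keeping their global influence weak — without
  this, Ant_Blunt and Com_Loc would acquire spurious first-order
  variance comparable to the leaflet lengths.
* **Anterior weight α = 2.5.** The anterior leaflet forms the major
  coaptation surface in systole; the weight also compensates AL's small
  absolute variance (AL spans only ≈ 3.5–14 mm) so that anterior length
  is influential per millimetre, as observed in valve mechanics.
* **δ_AP = 1.30.** The chord demand grows linearly with AP, but larger
  annuli also billow more leaflet tissue into the orifice; a supply
  exponent slightly above 1 makes the conditional mean E[OA | AP]
  nearly flat over the sampled AP range, so AP's *first-order* index is
  small even though AP participates in every term (its influence is
  routed through IC = IC_D_R·AP, AL, PL and CL instead).
* **δ_IC = 0.8.** A wider commissural span stretches the same leaflet
  tissue over a longer coaptation line, degrading sealing; this gives
  IC a strong effect beyond the trivial Δx ∝ IC factor.
* **Commissural leak.** leak(s) = κ·max(0, CL_ref − CL)·B(s)·gate, with
  Gaussian bumps B at s ≈ 0.1 and 0.9 (width 0.07), κ = 0.30,
  CL_ref = 14 mm: short commissures leak near the commissures, where
  the chord itself is too small to discriminate. The gate
  m̄/(m̄ + 1 mm) vanishes with vanishing leaflets so the zero-leaflet
  limit is exact.
* **Saddle penalty** c_h = 0.05, h_ref = 2.7 mm: taller saddles reduce
  efficiency by ≲ 2.5% — deliberately minor.

All constants live in `EmulatorConstants` and are frozen defaults;
changing them changes the study conditions.

Checkable consequences (all tested): zero-leaflet limit OA → π·AP·IC/4;
oversupplied leaflets give OA = 0; OA is non-decreasing in IC and
non-increasing in PL; the station closed form agrees with the
independent gap-length plane algorithm within 2% at 40 planes; and the
first-order Sobol indices of the emulator itself rank {IC, AL, PL, CL}
on top (typical values ≈ 0.5, 0.17, 0.2, 0.2 against ≤ 0.03 for every
other parameter). With λ ∝ AP^1.30 the joint c-scaling of all lengths
is only approximately quadratic in OA; exact dimensional behavior is
covered by the ellipse-limit test instead.

Because the emulator is smooth-plus-clamp, passing tests show that the
*pipeline* (surrogate, sensitivity estimator, density comparison)
recovers the structure a closure model induces; they do not validate
any particular finite-element model or patient anatomy.

## Gap-length orifice area

Edges are ordered 3D polylines. The coaptation line is estimated as the
midcurve of the two edges (resampled at 256 arclength points); planes
sit at midpoints of n equal cells of the midcurve's span along the
commissure-to-commissure axis (default n = 40), each with normal equal
to the central-difference midcurve tangent. Curve–plane intersections
are segment crossings with linear interpolation (all crossings kept);
the local gap is the minimum anterior–posterior point-set distance,
zeroed below 1e−12 mm (contact). OA = Σ gᵢ · Δx with Δx = span/n — the
per-plane gap sum is multiplied by the plane spacing because a sum of
lengths alone is not an area. A plane that misses one curve contributes
zero with a logged warning. The algorithm is exact for parallel
straight edges and rigid-motion invariant to 1e−9 relative.

## GP surrogate

Unit-amplitude ARD squared-exponential kernel; inputs stay in physical
units (length scales absorb scale), targets are standardized per
training fold. The jitter σ² = 1e−4 (standardized units) is fixed, not
optimized — it stabilizes the Cholesky factorization and regularizes
slightly. Length scales maximize the evidence by L-BFGS-B in log space
(bounds ±30 in log units, analytic gradients), from the CV-chosen init
plus 2 jittered restarts (log-normal, sd 0.3); the best evidence wins.
The CV grid multiplies the per-dimension input range by
{0.1, 0.316, 1, 3.16, 10} and scores each candidate by mean held-out R²
over 5 folds; ties go to the smaller init. For the refit on all
samples, the init chosen most often across the five splits is reused.

MAPE divides by y, so targets with |y| < 1e−6 mm² (fully coapted
valves) are excluded from the MAPE sum with a logged count. R² for a
zero-variance target is an error unless predictions are exact (then 1
by convention). A degenerate constant-target GP predicts the constant.

## Sobol estimator

The fix-one-dimension scheme: for each dimension d, n_outer fixed
values are taken from the d-th column of a joint sampler draw; each is
combined with n_inner fresh joint samples whose d-th coordinate is
overwritten; V_d is the variance (ddof = 1) of the n_outer inner means
and Var(y) is pooled over all n_outer·n_inner·D evaluations (the
denominator choice is a package convention). Overwriting a physical
coordinate breaks the dependency induced by unnormalization (fixing AP
does not re-fix IC = IC_D_R·AP in the inner draws); this literal
fixing is intentional and documented. The estimator carries an upward
bias of order Var(y)/n_inner in each V_d (inner-mean noise), negligible
at the budgets used. Raw indices may be slightly negative; they are
clipped at zero only in ranked summaries. Draw order is documented so
an exact-replay brute-force loop can reproduce it to 1e−12.

Densities are 100-bin equal-width histograms on a common grid spanning
the pooled range of all compared sample sets (histograms rather than
KDE for a stable, exactly normalized TV); TV(p, q) = ½ Σ|pᵢ−qᵢ|·Δ.

## Experiment protocol and problem sizes

Defaults: 440 emulated valves; five independent random 350/90 splits;
5-fold CV for the GP init; GP refit on all 440; Sobol at
1000 × 1000 per dimension (12 M surrogate evaluations) for the CLI
default, 500 × 500 (3 M) in the acceptance script and test suite — the
indices differ by well under the ranking margins at either budget;
densities from 20 000 fresh surrogate evaluations. "Mean values" for
the fixed parameters in the 4-parameter density are empirical means of
the physical parameters from 1e5 seeded draws (the unnormalization is
nonlinear, so these differ from range midpoints; a midpoint mode is
available). The master seed spawns independent child seeds per stage
(dataset, splits, CV, fits, Sobol, means, densities), so every stage is
individually reproducible and the JSON report is byte-identical across
runs.

## Limitations

* The emulator is kinematic: no stresses, no chordae or papillary
  geometry, no post-repair (device) configurations, no flow. Its
  sensitivity structure is imposed by construction; conclusions about
  real valves require a physics-based closure model in its place.
* First-order indices only; interaction (higher-order/total) effects
  are not estimated.
* The per-split GP/linear comparison uses a single response (orifice
  area); other outputs (e.g. leaflet stress) would rank parameters
  differently.
* MAPE is unstable when many valves nearly coapt (targets near zero);
  the exclusion threshold makes it well-defined but it remains a
  heavy-tailed metric on this population.
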