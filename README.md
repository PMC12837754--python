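# mvsens

**Which features of mitral valve geometry drive the regurgitant orifice
area?** `mvsens` is a Python package for answering that question with a
surrogate-based global sensitivity analysis. It is aimed at researchers
in cardiac biomechanics who parameterize the mitral valve by a small set
of anatomical measurements — the kind obtainable from echocardiography —
and want to know which of them matter for valve closure.

The pipeline:

1. **Geometry** (`mvsens.valve_geometry`). The valve is described by 12
   parameters: anteroposterior annular diameter AP, intercommissural
   diameter IC, anterior/posterior leaflet lengths AL and PL, commissure
   length CL, annular saddle heights AH and PH, and five shape factors
   (leaflet bluntness, annular D-shape, septal flatness, commissure
   location and curvature). Samples are drawn uniformly in normalized
   (ratio) form and unnormalized to mm scale, e.g. IC = IC_D_R · AP,
   PL = PL_R · (AP − AL), CL = CL_R · (PL − PH).
2. **Closure emulator** (`mvsens.closure_emulator`). A deterministic
   kinematic closure rule maps each parameter vector to a per-station
   coaptation gap profile and an orifice area (OA). It is an
   analytically checkable synthetic stand-in for a finite-element
   closure simulation, constructed so that OA variability is dominated
   by IC, AL, PL and CL.
3. **Gap-length orifice area** (`mvsens.orifice_area`). Given anterior
   and posterior free-edge curves, 40 equally spaced planes are cut
   perpendicular to the local coaptation line; the OA is the Riemann sum
   of per-plane minimum gap lengths times the plane spacing.
4. **GP surrogate** (`mvsens.gp_surrogate`). An automatic-relevance
   kernel k(xᵢ,xⱼ) = exp(−½ Σ_d (x_{i,d}−x_{j,d})²/l_d²) with a small
   fixed jitter σ²; length scales maximize the log marginal likelihood,
   with the initial guess chosen by 5-fold cross-validation. A linear
   least-squares baseline is fit on the same splits; both are scored by
   test R² and MAPE.
5. **Sobol sensitivity** (`mvsens.sobol_sensitivity`). First-order
   indices S_i = V_i/Var(y) with V_i = Var(E[Y|X_i]) estimated by the
   fix-one-dimension Monte-Carlo scheme, plus histogram densities and
   the total-variation distance TV(p,q) = ½∫|p−q|dx between orifice-area
   distributions.
6. **Pipeline & CLI** (`mvsens.pipeline`, `mvsens` command). End-to-end
   orchestration: 440 valves, five random 350/90 train/test splits, GP
   refit on all samples, Sobol ranking, and a three-way density
   comparison (emulator truth vs GP with all 12 parameters vs GP with
   only the top-4 varying, the rest fixed at their means).

## Worked example

```sh
mvsens run --seed 1 --outdir out
```

prints

```
mean GP test R2 0.997, linear 0.926
top-4: IC, CL, AL, PL
TV(GP4, GP12) = 0.060
wrote out/report.json
```

Reading: over five random 350/90 splits of 440 emulated valves the GP
surrogate explains 99.7% of held-out orifice-area variance versus 92.6%
for the linear baseline (the closure response is nonlinear — leaflet
contact clamps the gap at zero). The four parameters with the largest
first-order Sobol indices are the intercommissural diameter, commissure
length, anterior leaflet length and posterior leaflet length; a GP that
varies only those four (fixing the other eight at their means) produces
an orifice-area distribution within total-variation distance 0.060 of
the full 12-parameter distribution, i.e. four anatomical measurements
carry almost all of the geometric information about OA.

The same experiment is available stage by stage (`mvsens generate`,
`fit`, `sobol`, `densities`), configured via `--config config.yaml`
(see `mvsens.pipeline.ExperimentConfig` for the schema and defaults).

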