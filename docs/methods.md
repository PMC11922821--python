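# Methods

## The cell circuit

The model couples myofibroblasts `F` and macrophages `M` through two
growth factors. `c21` (the myofibroblast growth factor, e.g. a
TIMP1-like autocrine signal) is produced by myofibroblasts at rate β11
(autocrine) and macrophages at β21 (paracrine) and drives `F`
proliferation through a saturating Michaelis–Menten term
`c21/(k21+c21)`; `c12` is produced by myofibroblasts at β12 and drives
`M` proliferation. Both factors are removed by receptor-mediated
endocytosis (α terms, saturating in the factor, proportional to the
consuming cell count) and by first-order degradation γ. `F` carries a
logistic carrying capacity `K`; `M` has none, so a parameter regime with
unbounded `M` is reported as outcome `other` rather than clipped.

Reference parameter values (packaged as `data/wildtype.json`):
β12 = 6,768, β11 = 345,600, β21 = 100,800 molecules/cell/day;
α12 = 1,353,600, α21 = 734,400 molecules/cell/day; γ = 2/day;
k12 = 3.6×10⁹, k21 = 1.3×10⁷ molecules; λ1 = 1.08, λ2 = 0.8/day;
μ1 = μ2 = 0.3/day; K = 10⁶ cells. In this regime macrophage
proliferation cannot be self-sustained (`λ2·h12 < μ2` for any reachable
`F`), so the only attractors are the healing origin and the
macrophage-free cold-fibrosis state — bistability without a hot state.

**Healing means extinction.** The equations admit only `F = 0` as the
fibroblast-free state; we adopt that literally rather than inventing a
small homeostatic baseline. Outcome classification uses thresholds
θ_F = θ_M = 10⁻²·K (any small positive cutoff separates the attractors;
the value is configurable and echoed in outputs).

## Numerics

- **Integration**: LSODA with analytic Jacobian, rtol 10⁻⁸, per-variable
  atol (10⁻⁶ cells, 10⁻³ molecules) — the state spans ~10⁰–10¹¹, so
  per-variable absolute tolerances matter. A terminal event stops
  integration once the scale-free criterion
  `max_i |dx_i/dt|/(|x_i|+1) < 10⁻⁶` is met, else at the 1000-day
  horizon. Reported states are clipped at zero (the field itself
  preserves non-negativity; clipping removes solver round-off only).
- **Initial conditions**: the growth factors equilibrate faster than the
  cells, so phase-portrait initial conditions are `(F0, M0)` with `c12`,
  `c21` at their quasi-steady values — unique non-negative roots of the
  scalar production/loss balances, bracketed on `[0, production/γ]`
  (the loss side is strictly increasing). The default acute-injury state
  is `F0 = 0.05 K`, `M0 = 0.5 K`: a macrophage-dominated transient in
  which infiltration has already occurred. With the reference
  parameters, `dM/dt > 0` would require `F > 0.64 K`, which no injury
  trajectory reaches — so the macrophage *rise* of an acute injury is
  represented by the initial condition itself and the simulated dynamics
  show its resolution.
- **Fixed points** are found by exact branch reduction rather than blind
  4-D root-finding: the origin; the macrophage-free branch, whose `F`
  values are roots of `λ1·Φ(F) = μ1` with
  `Φ(F) = h21(c21_qss(F))·(1−F/K)` (1-D bracketing scan + Brent); and
  the coexistence branch, where `dM/dt = 0` pins
  `c12* = μ2·k12/(λ2−μ2)` and the remaining residual is again scalar in
  `F`. A branch with `F = 0, M > 0` is impossible because `c12` is
  produced only by `F`. Stability comes from the analytic Jacobian's
  eigenvalues with a 10⁻⁸/day real-part tolerance; marginal points are
  flagged as `other` and conservatively counted as existing when
  deciding whether the cold state persists (saddle-node caution).
  Forward integration from perturbed starts serves as an independent
  oracle in the tests.
- **Threshold scan**: decrease fractions x of λ1 (default; β11
  available) are scanned upward at the requested resolution; for each x
  both criteria are evaluated — does the default injury simulation heal,
  and does a stable cold fixed point still exist. Because Φ does not
  depend on λ1, the λ1 saddle-node admits the closed form
  `x* = 1 − μ1/(λ1·max_F Φ)` ≈ 0.39998 with the reference values; the
  1% grid therefore reports 40% for the fixed-point criterion and 41%
  for the simulation criterion (at exactly x = 0.40 the saddle-node
  ghost makes the transient slower than the horizon). Optional bisection
  refinement narrows the fixed-point threshold to 10⁻³.
- **Basin maps**: default grid is log-spaced over `[10², 1.2 K]` plus
  the zero axis, 50×50, in both `F` and `M`; each point is initialised
  at quasi-steady factors, integrated to steady state and labelled.
  Integrator failure at a point labels it `other` with a warning rather
  than aborting the map. The separatrix is the healing/non-healing
  boundary with midpoint interpolation between adjacent grid points of
  differing label, ordered by angle around the centroid.
- **Convex archetype decomposition** solves
  `min ‖G_c − Σθ_i G_i*‖²` on the simplex by active-set NNLS on the
  system augmented with a heavily weighted sum-to-one row
  (weight 10⁶ × data scale), followed by exact renormalisation; for any
  point inside the simplex the residual is far below the 10⁻⁸
  tolerance. Argmax ties in the closest-archetype assignment break to
  the lowest index for determinism.

## Quantification conventions

- Neighborhoods are closed disks of radius 50 µm (configurable) around
  each cell, *including* the focal cell, so percentage denominators are
  never zero; percentages are out of the in-disk total. No edge
  correction is applied by default (matching a per-FOV averaging
  workflow); an optional border-exclusion margin drops focal cells near
  the FOV boundary while still counting them as neighbors — used where
  unbiased comparison to the Poisson expectation `λ·πr²` is needed.
  Distances are 2-D Euclidean on µm coordinates.
- Aggregation is two-level and unweighted: cell profiles are averaged
  per FOV, FOV means per animal, so large FOVs do not dominate.
- The cold/hot region call uses myofibroblast:macrophage ratio cutoffs
  r_cold = 3 and r_hot = 2 — operational values anchored between the
  observed ≈6:1 (cold infarct) and ≈1:1 (hot) regimes; both are
  configurable and echoed in outputs. Zero macrophage means with
  myofibroblasts present count as infinite ratio (cold, flagged).
- Cell-type signature scores are the *mean* fractional expression over
  marker genes; archetype signature scores are the *sum* (the
  signature's share of the transcriptome). The two modes are kept
  explicit rather than unified. Missing signature genes are dropped
  with a warning (symbol mismatches across species are the realistic
  failure mode); the supplied matrix defines the gene universe.
- Zone fold changes average replicates within (condition, timepoint,
  zone) first, then ratio infarct/remote group means. Group comparisons
  use the exact Mann-Whitney test for small n, asymptotic beyond 20 per
  group, with Bonferroni multiplication by the number of planned
  comparisons capped at 1.
- The proliferation score retains cells with total counts in
  [10³, 10⁴] (inclusive) and is the retained cell's cell-cycle count
  fraction. Pearson correlations use the standard t-transform p-value.

## Synthetic data: what it does and does not emulate

Generators are pure functions of (config, seed) via
`numpy.random.default_rng`, byte-reproducible at fixed seed, and always
return ground truth next to the data.

- Tissue maps are independent homogeneous Poisson point processes per
  cell type (cold: 6:1 myofibroblast:macrophage intensity ratio; hot:
  1:1; optional suture disk with boosted macrophages), chosen so the
  neighborhood estimator's expectations are closed-form
  (`λ_t·πr²`, +1 for the focal cell's own type by Slivnyak's theorem).
  Real tissue has cell-size exclusion, clustering and anisotropy; tests
  passing on Poisson maps validate the estimator arithmetic, not
  robustness to those structures.
- Bulk samples are multinomial draws (default depth 10⁶, which keeps
  counting noise well inside the ±10% recovery tolerance at n = 4) from
  mixtures of cell-type profiles with disjoint marker blocks — no
  cross-hybridising markers, batch effects or length biases. Default
  infarct folds encode the cold time course: macrophage 3 → 1,
  myofibroblast 4 at both timepoints (a clearly
  myofibroblast-dominated infarct, chosen off the region-call decision
  boundary).
- Single cells are Dirichlet-weighted convex combinations of Gaussian
  archetype positions plus isotropic noise, with a late-day Dirichlet
  shift toward one archetype; ligand tables carry a dominant
  myofibroblast autocrine activity block by construction.
- Trajectory observations apply multiplicative lognormal noise of given
  CV to the exact simulation.

## Problem sizes used in tests and drivers

Basin analyses use the 50×50 default grid; the grid-refinement test
checks that the wild-type healing fraction moves by < 0.05 when the
grid density doubles (12×12 vs 24×24). Poisson-map checks use 20 seeds of 800-µm FOVs
and 50 replicate cold/hot classifications; deconvolution recovery uses
the full 2×2×2×4 design at depth 10⁶. These sizes are the package's
defaults for desk-scale validation.

## Known limitations

- The bifurcation scan assumes outcome monotonicity in the decrease
  fraction (asserted over each scan); non-monotone regimes would need a
  full scan without early exit.
- `find_fixed_points` relies on the branch factorisation of this
  specific circuit; structurally different models would need the
  generic multi-start path.
- The simulation-criterion threshold depends on the injury initial
  condition and horizon; both are configurable, and the fixed-point
  criterion is reported alongside as the protocol-independent quantity.
- No 3-D coordinates, no interacting point processes, no read-level
  sequencing simulation.
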