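# Methods

## Model

`qsflock` integrates a 4N-dimensional ODE system for N cells in the plane.
Each cell i carries position `x_i ∈ ℝ²`, velocity `v_i ∈ ℝ²`, QS protein
level `p_i ≥ 0` (AU) and local autoinducer concentration `A_i ≥ 0` (AU).
Protein and autoinducer are scalars: every balance equation and every
diagnostic (histograms, thresholds) treats them as levels, not vectors.

Velocities and protein levels relax toward distance-weighted population
averages (Cucker–Smale flocking terms with weights
`k(x_i,x_j) = 1/(1+|x_j−x_i|²)^β`, β ≥ 0) plus source terms: a chemotactic
drive `F₀(v₀ê_s − v_i)` toward the attractant direction `ê_s` and an
expression drive `L₀(p_∞ − p_i)Ψ_A(A_i)` gated by a logistic switch on the
autoinducer level. The autoinducer balance is synthesis minus uptake minus
degradation: `dA_i/dt = λ₃ Σ_j k₃(x_i,x_j) r − k_u A_i − k_d A_i`. Note the
synthesis sum deliberately carries no 1/N factor, unlike the velocity and
protein flocking terms; `normalize_synthesis=True` restores it for
sensitivity studies. All pairwise sums include the self term j = i: the
self-weight is 1, the flocking differences vanish at j = i, and the
synthesis and density sums gain a well-defined single-cell floor.

In the coupled variant the chemotactic target speed interpolates between
`v₀` and `v_∞` through a second logistic switch on the cell's own protein,
`Ψ_p(p_i)`. Setting `Ψ_p ≡ 0` recovers the uncoupled model exactly (this is
a tested identity, bitwise at the level of the right-hand side). Protein
degradation is omitted (assumed minimal); adding it is a one-line extension
point noted in `dynamics`.

Three uptake-rate models are available:

* `distance_sum` (default): a shifted Gaussian in
  `S = γ₁ Σ_j |x_j−x_i|^(2β_u)`, i.e.
  `k_u = a₁ exp(−(aS−b)²/(2c)) + a₂`. Uptake rises with density to a peak
  and falls off under overcrowding (reduced metabolic activity), never
  dropping below the floor a₂. The exponent β_u has its own parameter but
  defaults to the kernel β, since the motivating scenario uses a single β
  for both roles.
* `kernel_density`: the same Gaussian driven by `D = γ₂ / Σ_j k₃(x_i,x_j)`
  — the inverse of the kernel sum, so crowded cells have small D. A
  `literal_formula` flag switches to `D = γ₂ Σ_j k₃` for comparison; the
  inverse form is the default because the density measure is meant to be
  the inverse of the kernel sum. The self-term guarantees `Σk₃ ≥ 1`, so the
  division is always safe.
* `logistic_time`: a four-parameter logistic ramp
  `k_min + (k_max−k_min)/(1+exp(−rate·(t−midpoint)))`, the variant used for
  asymptotic analysis; with it the autoinducer level converges to the
  constant `λ₃ Σk₃ r/(k_max + k_d)` (tested at N = 1). The exact parametric
  form of this ramp is a package choice — only its monotone saturating
  limits matter to the convergence property.

All logistic evaluations go through `log1p/logaddexp`, so extreme arguments
saturate exactly at 0/1 instead of overflowing.

## Integration

Initial populations are i.i.d. uniform over configurable position/velocity
boxes (numpy PCG64; the seed fully determines a run, and outputs embed it).
Protein and autoinducer start at 0 by default so QS expression emerges from
the dynamics. Integration uses scipy's adaptive embedded Runge–Kutta 4(5)
(`RK45`) with rtol = atol = 1e−9, sampling a uniform time grid (endpoints
included) through dense output. Tolerance halving moves default-fixture
final states by < 1e−7, and the sample grid does not affect the final state
beyond integrator tolerance (both tested). Integration failure (step-size
underflow) raises an explicit error with the integrator message — never a
silently truncated trajectory.

## Diagnostics

* **Flocking** (Motsch–Tadmor sense): velocities must converge while
  pairwise distances stay bounded. On a finite horizon the verdict is
  `Dv(t_final) ≤ convergence_ratio · Dv(0)` (default 1e−3) and
  `max_t Dx(t) ≤ bound_factor · Dx(0)` (default 10), with `Dv`, `Dx` the
  exact max-over-pairs Euclidean diameters. A population starting at zero
  velocity spread counts as flocked iff it stays bounded.
* **Mode counting**: fixed 20-bin equal-width histogram over [min, max]; a
  mode is a bin strictly exceeding both neighbours and 10 % of the tallest
  bin. A sample whose spread is below numerical resolution (range ≤ 1e−6
  relative) is one mode by definition — without this guard a fully
  saturated population would be histogrammed at integrator-noise scale.
  With N = 100 and 20 bins, Poisson noise on a broad unimodal sample can
  still produce an occasional spurious small mode at transient times; the
  bimodality verdict is therefore read at late time, when the expresser /
  non-expresser split dominates.
* **Subgroups**: deterministic 2-means on scalar speeds, centroids
  initialised at the min and max speed. Two groups are reported only when
  the mean-speed gap exceeds 2 pooled within-group standard deviations
  *and* 5 % of the population mean speed. The second gate exists because
  the separation ratio alone is scale-invariant: any continuous unimodal
  speed sample — including pure numerical noise around a consensus speed —
  splits at a ratio near 3, which would misreport one aligned flock as two
  groups.
* **Density–expression association**: Spearman rank correlation between the
  per-cell kernel density `Σ_j k(x_i,x_j)` and `p_i`. Rank, not linear,
  because the density→expression chain runs through a Gaussian and a
  logistic — monotone within a regime but far from linear. Zero variance in
  either variable yields NaN (undefined), distinct from an error.

## Default parameter fixtures ("fig-defaults")

A handful of constants are fixed by the scenarios themselves: the consensus
run's λ₁ = 5, β = 0.2, N = 100 and velocity boxes [0,20]×[0,30]; the
expression runs' Gaussian-uptake constants a = 4, b = 4, c = 27.81 with
β = 0.62 and γ₁ = 1/2000; the 0.7 AU GFP threshold; rtol = atol = 1e−9.
Everything else was chosen once, by manual tuning, so that each scenario
sits robustly inside its intended qualitative regime (verified across
several seeds), and is not revisited:

* `v₀ = 10`, `ê_s = (1,1)/√2`, `F₀ = 1`: the consensus target. With F₀ = 1
  the velocity spread contracts at unit rate, so `t_final = 15` leaves a
  huge margin on the 10³-fold contraction requirement.
* Expression runs: positions uniform on [0,30]², chosen so that `a·γ₁·S`
  spans the Gaussian peak at b = 4 — the crowded half of the population
  sits near the peak (high uptake) and the periphery on the flank. At
  β = 0.55 the population sits left of/at the peak and crowded cells, with
  their larger synthesis sums, accumulate more autoinducer (positive
  correlation); by β = 0.7 the typical `a·γ₁·S` has moved far right of the
  peak and the relationship inverts. Initial velocities [0,5]² keep early
  transients from scrambling the geometry. `λ₃ r = 0.1`, `k_d = 0.1` place
  steady-state autoinducer levels in [0.45, 0.8]; the expression switch
  (steepness 100, threshold 0.6) bisects that spread sharply, which is what
  makes the late-time protein distribution cleanly two-moded. `λ₂ = 0.1`
  keeps protein averaging weak enough not to erase the split.
* Subgroup run (coupled, equal switch exponents α₁ = α₂ = 1): starts from
  an already-marching population (velocities jittered around `v₀ê_s`) —
  the emergent story is a subgroup accelerating out of an aligned flock,
  and an aligned start also makes the uncoupled control's verdict (one
  group at every time) exact rather than accidental. `v_∞ = 30` gives the
  expressers a 3× speed contrast. Slow expression (`L₀ = 0.2`) and a high
  motility threshold (Ψ_p threshold 0.8) widen the window in which the
  early-deciding expressers have split off while the left-behind group has
  not yet accumulated enough protein to follow; `t_final = 16` reads the
  verdict inside that window. The split is transient by mechanism: once
  the fast group departs, the stragglers' distance sums blow up, their
  uptake falls to the floor, and they eventually express and accelerate
  too — the model has no latch that would make the partition permanent.
* Transwell run (coupled, α₁ < α₂): motility switch trips at p = 0.05 with
  exponent 1 while the expression switch needs A ≈ 0.5 with exponent 2 —
  motility is strictly the more sensitive response. Cells start near the
  origin ([0,10]²), the membrane is the line `x·ê_s = 60`, speeds are
  v₀ = 2 / v_∞ = 6, and sampling every 8 AU to t_final = 48 brackets both
  transitions: crossings reach half-maximum at t = 16, the GFP-positive
  fraction at t = 32. Crossing is cumulative (once past the membrane,
  always counted; the ODE system is unchanged — cells are counted, not
  removed), while GFP positivity is instantaneous `p > 0.7` among crossed
  cells, mirroring how recruitment assays count migrated cells versus
  expressing fraction.

## What the generator emulates — and does not

The synthetic populations are uniform boxes of independent cells: they
reproduce the modelled phenomena (consensus, bimodality, reversal,
splitting, sequential migration/expression) but none of the biology the
model abstracts away — no cell division or death, no run-and-tumble
stochasticity, no spatially resolved autoinducer diffusion field (each cell
carries its own local concentration), no nutrient depletion beyond the
phenomenological uptake Gaussian, and arbitrary units throughout (no
mapping from AU to hours or micrometres). A green test therefore
establishes that the *model* produces a regime, not that real cells do.

## Known limitations

* The ODE system is O(N²) per right-hand-side evaluation; N in the
  hundreds is comfortable, N ≫ 10⁴ is not the design point.
* The qualitative verdicts (modes, subgroups) use fixed, documented
  detector thresholds; distributions engineered to sit on a threshold
  boundary will flip with the seed. Detector parameters are exposed.
* `RK45` is a non-stiff method, matching the smooth dynamics here; extreme
  switch steepness (≳10³) with large rate constants may need smaller
  tolerances or a stiff solver, which is out of scope.
* The transwell geometry is the 1-D projection on `ê_s`; there is no
  physical membrane, chamber volume, or cell removal.
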