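# Methods

## Model and assumptions

The object of study is the stationary behavior of a four-state promoter
cycle: substrate S, TF-bound X, polymerase-bound P, doubly bound XP, with
eight first-order transitions.  Assumptions baked into the model:

* **Timescale separation.**  Binding/unbinding equilibrates fast relative to
  transcription, so gene output is proportional to the stationary occupancy
  of transcriptionally potent states.  Only stationary distributions are
  computed; there is no trajectory (Gillespie) simulation.
* **Single control variable.**  The TF concentration is the control knob,
  dimensionless as `x = [X]/1 nM`; it multiplies exactly the two TF-binding
  rates (`k_sx`, `k_p_xp`).  Polymerase concentration is constant and folded
  into `k_sp` and `k_x_xp`.  Because each cycle direction contains exactly
  one TF-binding edge, `x` does not affect the cycle affinity: concentration
  and drive are independent dials.
* **Strong connectivity.**  All rates are strictly positive, so the chain has
  a unique stationary distribution for every `x > 0`.

Stationary probabilities come from the Matrix Tree Theorem: `p_i ∝ Σ_trees
rooted at i Π(edge rates)`.  Trees are enumerated by brute force over
(N−1)-edge subsets — exhaustive, transparent, and instant for N ≤ 6, which
covers every graph this package analyzes; the same enumeration powers the
generic evaluator for square-equivalent variants (any graph whose spanning
trees carry at most two powers of `x`).  An independent oracle solves the
null space of the column-sum-zero rate matrix (`scipy.linalg.null_space`)
and agrees with the tree route to 1e-9 relative in the test suite.

## Shape analysis

Every observable is `(A + Bx + Cx²)/(D + Ex + Fx²)` with coefficients
assembled from potency-weighted tree weights grouped by TF-degree.  Shape
questions are posed on `u = ln y`, `y = x/√(D/F)`:

* slope: `d⟨r⟩/du = y·M(y)/den(y)²` with `M` quadratic — interior extrema
  are positive roots of `M`;
* curvature: `d²⟨r⟩/du² = y·q(y)/den(y)³` with `q` quartic — inflections
  are the odd-multiplicity positive roots of `q`.

Roots are companion-matrix eigenvalues (`numpy.roots`), Newton-polished
(companion estimates of roots spanning many decades can be off by factors of
two), merged at relative tolerance 1e-8, and validated by evaluating `q`
between candidate roots so that only genuine sign changes are counted — a
tangency (even multiplicity) never counts as a concavity change.

Numerical conditioning choices, in place of wholesale extended-precision
arithmetic:

* rescaling by `√(D/F)` makes the denominator `(1, b, 1)` — the analysis
  then only sees the intrinsic shape parameters, not raw tree-weight
  magnitudes (which stay within double range even at the 40 kBT budget);
* the leakiness (or saturation, whichever leaves the larger residual) times
  the denominator is subtracted from the numerator before differentiating —
  an exact shape invariance that removes the offset-cancellation error when a
  curve rides on a large constant;
* every product and difference in the construction of `M` and `q` carries a
  propagated rounding floor; a leading coefficient is discarded only when it
  is indistinguishable from zero at its own floor.  This distinguishes
  cancellation noise from genuinely small coefficients whose far-out roots
  are real curve features;
* a saturating rational curve must satisfy the parity relation
  (#inflections + #extrema) odd; if root finding violates it, counts are
  settled by sign evaluation on a 40001-point log grid spanning all
  coefficient-ratio scales, and the curve is flagged `boundary_case`;
* nonmonotonicity decisions in the drive scans use the interior-extremum
  test (quadratic `M`), which is sturdier than the quartic inflection count.

Degenerate (constant) responses are reported as such rather than classified.
One notable exact degeneracy: the all-unit rate set with transcriptional
potencies (0,0,1,1) has `p_P + p_XP ≡ 1/2` for every `x` by the S↔P, X↔XP
relabeling symmetry, so equilibrium reference checks use a symmetry-breaking
potency vector such as (0,0,1,2).

Sensitivity is `s(x) = |d⟨r⟩/du| / (⟨r⟩max − ⟨r⟩min)` with the extrema taken
over all `x` (endpoints plus interior extrema).  Since the slope vanishes at
both ends of the log axis and its stationary points are exactly the
inflections, the global maximum of `s` is read off the inflection roots — no
numerical optimizer is involved.

## Default parameters

| parameter | default | why |
|---|---|---|
| potencies `(r_s, r_x, r_p, r_xp)` | (0, 0, 1, 1) | transcription tracks polymerase occupancy |
| reference concentration | 1 nM | makes `x` dimensionless; all rates in s⁻¹ |
| drive budget | 40 kBT per edge | about two ATP hydrolyses — a conservative biological energy allotment |
| detailed-balance tolerance | 1e-9 on the log-ratio | far above double-precision noise for an 8-factor product |
| scan grids | 81 points (1D), 81×81 (2D), boundary bisection to 1e-3 kBT | resolves the narrow nonmonotonic bands some edges show |
| sampler window | 8 decades, log-uniform per rate | spans the kinetically plausible range and per-pair drives up to ~e±18 |
| equilibrium sampler energies | uniform ±4 kBT | binding free energies of a few kBT are typical for TF/polymerase–promoter contacts |

The shipped `plausible` default rate set is built from state free energies
(0, −2, −1, −5) kBT and forward rates (10, 0.1, 1, 5) s⁻¹ — detailed
balanced by construction, with rate magnitudes in the ranges typical of
transcription kinetics.  It deliberately has `k_x_xp > k_sp` *and*
`k_xp_x > k_ps`, i.e. the TF coherently raises both the polymerase binding
and unbinding rates: the configuration whose drive scans can reach
nonmonotonic responses.  The contrasting `diffusion_limited` fixture keeps
the same energies but sets `k_x_xp = k_sp` (TF does not alter the
polymerase's binding rate), which provably pins the response monotonic at
any drive.  These are implementer-chosen defaults within stated orders of
magnitude, not measured rate constants; quantitative scan optima (e.g. the
exact slope ceiling of a given edge pair, or which pairs tie rather than
beat single-edge driving) depend on them, while the structural results
(tree census, phenotype universality, sensitivity bounds, the monotonicity
criterion, boundary optima, the infinitesimal-vs-finite minimal-drive
dichotomy) do not.

## What the samplers emulate — and what they do not

The wide sampler draws each rate independently log-uniformly: it is a
coverage tool for rate space, not a model of any organism's kinetic
parameters.  The equilibrium sampler draws thermodynamically consistent sets
from random state energies.  Drive-targeted generation (equilibrium base
plus up to ±40 kBT on one random edge) populates the rarer multiply-inflected
classes.  None of these emulate measurement noise, finite molecule numbers,
nonstationary transients, or correlated rate variation, so passing tests
demonstrate properties of the model class — every mathematically reachable
curve shape, bound and phase boundary — rather than fits to any dataset.

## Design choices where the design was open

* **Boundary optima as computed facts.**  The pair-slope objective plateaus
  toward extreme drives, so an interior simplex search can stop anywhere on a
  flat ridge.  `optimize_pair_slope` therefore also maximizes along the four
  boundary slices and reports the boundary attainment whenever it matches the
  global maximum within 1e-9 relative.
* **Net drive for pair scans** is the cycle affinity of the modified rate
  set (signed sum of per-edge `dmu` by cycle orientation) — one definition
  that reduces to ±dmu for single edges with no case analysis.
* **Minimal-drive search** uses a deterministic zooming grid on the 2D
  budget box (bisection in 1D), refined to 1e-3 kBT by default, and returns
  `inf` as the sentinel when nonmonotonicity is unreachable in budget.
* **Repressive curves** (saturation below leakiness) are classified on the
  normalized orientation; inflection counts and `s_max` are invariant under
  affine potency maps and concentration rescaling (tested).

## Problem sizes used by the tests and the acceptance script

The default test run classifies ~1.5×10⁵ sampled curves in total: 10⁴ for
phenotype universality, 10⁵ (plus one-fifth drive-targeted and one-tenth
equilibrium) for the sensitivity bounds, 10³ paired against the
extended-precision grid oracle, 10³ for the tree-vs-nullspace invariant, and
all 28 edge pairs through the slope optimizer at a 21-point coarse grid.
`scripts/acceptance.py` uses 10⁵ samples over 8 decades for the sensitivity
floor.  These sizes give stable two-decimal statistics for the sampled
extremes while keeping a full run in a few minutes on one CPU.

## Known limitations

* Inflection counting is exact up to floating point, but curves *at* a phase
  boundary (coincident roots) are measure-zero and settled by multiplicity
  parity with a `boundary_case` flag; a dense-grid differencing oracle cannot
  resolve features whose curvature falls below ~1e-16 of the range, so
  classifier-vs-oracle comparisons exempt such marginal curves.
* The per-phenotype sensitivity bounds are verified empirically by wide
  sampling, not proved symbolically; the one-inflection floor is an
  empirical constant asserted at two-decimal precision, and whether it is
  attained or only approached is left open (the harness reports the observed
  minimum).
* Spanning-tree enumeration is exhaustive and intended for N ≤ ~10 states;
  no Laplacian-minor fast path is provided because no analysis here needs
  one.
* The CLI's PNG export is a convenience phase map, not a figure-production
  tool.
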