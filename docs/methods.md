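# Methods

## Model

`morphoridge` models the interface between two growing elastic layers — in
the motivating system, the stiff periostracum (layer 2) bonded to the softer
mantle edge (layer 1) of a mollusc's generative zone — as a planar curve
`y(S, t)` on the expanding domain `S ∈ [−L(t), L(t)]`.  The shape at each
instant minimises

    E[y] = ∫ (Eb/2) (y″)² + (K/2) f(y) dS,     f(y) = (y − ŷ)^m,

subject to the small-slope excess-length constraint `(1/2) ∫ (y′)² dS =
2δ(t)`, where `δ(t) = l(t) − L(t)` is the accumulated length mismatch
between the layers and `ŷ` is the (optionally remodelling) rest shape of the
foundation.  Growth is slow compared with elastic relaxation, so the system
is treated as quasi-static: each time slice is an independent constrained
minimisation linked to the previous one only through frozen pattern
structure (widths, counts) and the memory amplitudes.

Rather than solving the Euler–Lagrange boundary-value problem, the shape is
restricted to a sum of isolated Gaussian bumps

    y(S, t) = Σ_i a_i(t) exp(−(S − S_i)² / σ_i²),

with all bumps of one hierarchical level sharing a width `σ_k` and amplitude
`a_k`.  A bump's footprint is `4σ` wide; a pattern "fits" when the disjoint
footprints fit inside `[−L, L]`.  For separated bumps every integral has a
closed form:

    (1/2)∫(y″)² dS   = C_BEND a²/σ³,   C_BEND = (3/2)√(π/2) ≈ 1.8800
    (1/2)∫(y′)² dS   = C_LEN  a²/σ,    C_LEN  = √(π/8)      ≈ 0.6267
    ∫(y−ŷ)^m dS      = √(π/m) (a−â)^m σ     (co-centred ŷ, equal widths)

These constants are verified against adaptive quadrature in the test suite.
Absorbing them (rescaling amplitudes by `√C_LEN` and collecting the
stiffnesses into one dimensionless ratio `μ = K·√(π/m)·C_LEN^(1−m/2) /
(2 Eb C_BEND)`) gives the reduced problem used everywhere downstream:

    E = Σ_k N_k ( a_k²/σ_k³ + μ (a_k − â_k)^m σ_k ),
    Σ_k N_k a_k²/σ_k = 2 δ(t).

`morphoridge.energetics` exposes both conventions and the exact conversion.

## Amplitude minimisation as water-filling

With `u_k = a_k²`, the reduced energy is convex in `u` for `m ≥ 2` and the
KKT conditions give a water-filling structure: every active level shares the
constraint multiplier

    λ = 1/σ_k² + (m/2) μ σ_k² u_k^{m/2−1}      (memory-less form).

`u_k(λ)` is monotone, so the constrained minimiser is found exactly: the
m = 4 case is piecewise linear in λ and solved segment by segment in closed
form; m = 3 is piecewise quadratic; other exponents use a bracketed root
(`brentq`, xtol 1e−14).  The length constraint is therefore satisfied to
machine precision at every output time.  With memory the per-level
stationarity `λ = 1/σ² + (m/2) μ σ² (a−â)^{m−1}/a` is monotone in `a` on the
physical branch and is solved by vectorised bisection nested inside a
bracketed root on λ.

## Level onsets

A new level `k+1` (with `N_{k+1} = Σ_{j≤k} N_j − 1` bumps, one per gap of
the current intercalation sequence) appears when two conditions meet
simultaneously:

* **fit** — its bumps exactly fill the slack left by the frozen levels:
  `4 N_{k+1} σ_{k+1} = 2L(t) − Σ_j 4 N_j σ_j`;
* **marginal stability** — the multiplier reaches the zero-amplitude
  marginal cost, `λ(t) = q(σ_{k+1})`, with `q(σ) = 1/σ²` for `m > 2` and
  `q(σ) = 1/σ² + μσ²` for `m = 2`.

The crossing time is refined by bisection between grid points and the new
width is frozen there, so `a_{k+1}(t_{k+1}) = 0` and the amplitude grows
continuously.  For `m = 2` the level-1 width `σ_1 = μ^{−1/4}` is the global
minimiser of `q`, so the marginal condition can never be met: a linear
foundation force produces no hierarchy.  This is exact in the
implementation, not a numerical observation.

**Level-1 onset and mode.**  Eliminating `a_1` through the constraint gives
`E_1(σ) = 2δ/σ² + μ N₁^{1−m/2} (2δ)^{m/2} σ^{1+m/2}`, whose minimiser is

    σ_1 = [ 2 (2δ)^{1−m/2} N₁^{m/2−1} / (μ (1 + m/2)) ]^{1/(3+m/2)}

(`μ^{−1/4}` for m = 2; `∝ δ^{−1/5}` for m = 4, slowly varying).  With σ_1
fixed the energy decreases with the mode N₁, so the maximal fitting count is
selected.  Two conventions close the onset problem:

* For a schedule that starts from zero excess, the first time the fit holds
  is marginal, so the selected mode is the smallest one the solver accepts.
  We seed the hierarchy with `min_mode = 2` — the two-primary base state the
  intercalation series is defined from; a single bump leaves no gaps to
  intercalate into and is treated as pre-patterned.
* A schedule may carry an initial excess `δ0 > 0` ("observation starts after
  some excess has accumulated").  Then the onset is immediate, the domain
  holds several bumps with room to spare, and N₁ grows with μ (≈ μ^{1/6}
  for m = 4).  The morphospace scenario uses `L0 = 8, δ0 = 0.5` for this
  reason; all other study configurations keep `δ0 = 0`.

σ_1 is frozen at its onset value (widths never change once set).

## Memory / remodelling

The foundation rest shape relaxes toward the deformed shape at rate η:
within the Gaussian family this is one exponential per level,
`â′ = a + (â − a) e^{−η dt}`, applied by operator splitting after each
quasi-static minimisation (the order is switchable; the two orders agree to
a few per cent at dt = 0.01).  A newly bifurcated level starts at `â = 0`.
Remodelling lowers the marginal cost of already-deformed levels, which is
what preserves the amplitude ordering `a_1 ≥ a_2 ≥ …`; without it (η = 0)
the quartic system robustly exhibits hierarchy breaking, with `a_2`
overtaking `a_1` once λ exceeds `1/σ_1² + 1/σ_2²`.  One known transient:
with η > 0 a freshly bifurcated level can collapse back toward zero
amplitude (its excess is cheaper to store in the remodelled level 1); during
the collapse `â_k` can exceed `a_k` by ~1e−4.  The even-power interaction is
well defined there; the invariant `â ≤ a` holds wherever amplitudes are
non-decreasing.

## Spine dilation

A burst of secretion is modelled as `δ(t)` ramping rapidly while L is
frozen.  The pre-existing ridge pattern is generated from a level sequence
(e.g. 3.2.3.1.3.2.3): widths fall geometrically per level (ratio 0.5,
footprints filling the domain), and amplitudes carry the ordered geometric
profile of the memory-preserved ridge phase (ratio 0.5, normalised so the
pattern holds the ridge-phase excess, default `δ_ridge = 0.05 L`).  We
prescribe this profile rather than re-running the memory-less minimiser
because the latter zeroes the higher ridge levels at small δ.

Two dilation pathways are compared at matched `δ(t)`:

* **linear** — each ridge amplifies in place with its ridge width; recorded
  ridge amplitudes are floors (the shell cannot un-record a ridge), and a
  level only amplifies past its floor once λ exceeds its marginal cost —
  in dense patterns the higher levels never amplify.
* **fractal** — each level-1 ridge becomes a root spine of width
  `4σ_root = 2L/N_root` (its full domain segment); deeper levels attach as
  children on parent flanks, activating once the parent amplitude reaches
  `factor · σ_child` (factor 4 by default, the footprint convention applied
  to the flank).  Tree policies: "chain" (one level-2 child on a root flank,
  deeper levels on both flanks of their parent) or "both".

Both pathways minimise under an additional hierarchy constraint
`u_1 ≥ u_2 ≥ …` (pool-adjacent-violators merging on the water-filling):
during the burst the recorded hierarchy is rigid, standing in for the memory
mechanism on the fast time scale.  Total energies are additive over bumps in
both pathways; the lower final-time energy selects the pathway.  The
crossover with ridge density emerges from the scalings: bending ∝ a²/σ³
punishes narrow ridges (dense → fractal wins), the substrate term ∝ σa⁴
punishes the wide root (sparse → linear wins).

## Reference oracles

Two progressively less constrained minimisations validate the reduction at
matched δ on the same discrete functional (finite-difference `y″`, trapezoid
quadrature, clamped-flat ends `y = y′ = 0`):

* overlapping Gaussians: joint SLSQP over all `(a_i, σ_i, S_i)` with cross
  terms by quadrature, multi-started from seeded perturbations of the
  separated solution (fixed seed; the unperturbed start is always a
  candidate, so the result never exceeds the separated energy);
* free nodal profile: SLSQP over all interior heights with the analytic
  gradient, started from the Gaussian profile, with the one-sided constraint
  `y ≥ 0`.  One-sidedness is part of the model (the layer deforms away from
  the foundation; the Gaussian family encodes this by construction) — without
  it the even-power interaction admits sign-oscillating minimisers that the
  physical system cannot reach.

Each family contains the previous one, so `E_full ≤ E_overlap ≤
E_separated` is a true restriction bound; every candidate profile is
rescaled to satisfy the discrete constraint exactly before comparison.  On
the validation configuration (m = 4, μ = 3, g = 1, L0 = 1) the
overlap-allowed amplitudes track the closed form to within ~2% throughout
the pre-bifurcation window; the free profile flattens the peaks by ~4–5% in
the separated regime (the first half of the window) and departs further as
the level-2 reorganisation approaches — the reduction is a restriction and
its error grows exactly where the separated-bump assumption stops applying.
Grid-refinement convergence of the free minimisation is below 0.1% per
halving when warm-started from the coarser solution.

## Study configurations (and what they do not emulate)

The study conditions are the package's own choices, fixed once:

| scenario        | parameters                                        |
|-----------------|---------------------------------------------------|
| hierarchy       | m=4, μ=10, L0=1, g=1, growth rate 1, t_max=20, dt=0.01 |
| memory          | as hierarchy, max_level=2, horizon 8, η ∈ {0, 0.5} |
| validation      | m=4, μ=3, otherwise as hierarchy                  |
| no-bifurcation  | m=2, μ ∈ [0.1, 100], g ∈ [0.01, 10] (log grids)   |
| dilation        | m=4, μ=1, sequence 3.2.3.1.3.2.3, L ∈ {3, 1}, burst g=5 |
| morphospace     | m=4, L0=8, δ0=0.5, μ ∈ {1,3,10,30}, g ∈ {0.5,1,2,4} |

These runs are dimensionless and noise-free: they exercise the mechanics of
intercalation, ordering and pathway selection, not biological variability.
In particular they do not model spatial heterogeneity of material
properties, stochastic secretion, finite mantle thickness, or the coupling
of the pattern to three-dimensional shell geometry (surfaces are dressed
onto smooth generating curves purely for visualisation).  Passing tests
therefore demonstrate the internal consistency and the qualitative
morphological predictions of the reduced model, not quantitative agreement
with any particular shell.

## Numerical choices

* Time marching: uniform grid, default dt = 0.01 (dimensionless); onset
  times refined by bisection/`brentq` to xtol 1e−12 within the bracketing
  step; widths frozen at the refined time.
* Water-filling multiplier: exact segment solve for m = 4; `brentq` with
  xtol 1e−14 otherwise; length conservation ≲ 1e−12 relative in all runs.
* Ties at a bifurcation are broken toward zero amplitude (the subcritical
  branch is never selected).
* Degenerate inputs: μ = 0 raises a "no foundation" error (the width
  optimisation diverges); a domain too small for one bump raises a
  pre-buckling error; infeasible floor/excess combinations raise before any
  state is mutated.
* Oracle discretisation: n = 401 nodes by default (≥ 16 nodes per smallest
  footprint), SLSQP with analytic gradients for the nodal problem.
* The only stochastic component anywhere is the oracle multi-start
  perturbation; it is driven by a single seeded generator.

## Known limitations

* The quasi-static marching assumes δ(t) non-decreasing; shrinking excess
  (resorption) is not supported.
* For m = 3 the memory solver restricts amplitudes to `a ≥ â` (odd powers of
  a negative deviation are not regularised away).
* The fractal child-placement and flank-fit rules are reconstructions
  (configurable policies), not derivations; only their energetic
  consequences are validated.
* The free-profile oracle finds local minima near the tracked branch; global
  structure (e.g. mode jumping far from the branch) is outside its scope.
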