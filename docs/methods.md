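# Methods

## Model and persistence criterion

Communities follow generalized Lotka–Volterra competition dynamics
`dN/dt = N ∘ (r − A N)` with nonnegative interaction strengths and strictly
positive self-regulation on the diagonal. Persistence is operationalized as
**feasibility**: the interior equilibrium `N* = A⁻¹ r` must be
componentwise strictly positive. Local dynamical stability of that
equilibrium is deliberately *not* part of the criterion — the experiment
records extinction avoidance at the recomputed equilibrium only. A
feasible-but-unstable equilibrium therefore counts as persistent; users
who want the stricter criterion can test eigenvalues of the community
matrix on the returned equilibria themselves.

The positivity threshold is exactly 0 with strict inequality
(`is_feasible(..., eps_pos=...)` exposes it for borderline studies); the
Monte Carlo estimators treat any equilibrium component within 1e-12 of 0
as outside the cone, implementing the open-cone definition under floating
point. A matrix with 2-norm condition estimate above 1e12 is declared
degenerate and rejected (the experiment resamples such draws and counts
them).

## Synthetic communities

The generator emulates paired 21-species competition communities that
differ only in how interactions are arranged:

- **Link budget.** All structures built from one configuration share the
  off-diagonal link count `L = round(connectance · n(n−1)/2)`. Matching
  the budget (not only the strength moments) isolates the *arrangement*
  of interactions as the experimental variable.
- **Modular** (default 3 modules of 7): the budget is split so the
  within-module link probability is `within_between_ratio` (default 8)
  times the between-module probability, then links are placed uniformly
  within each class. Unreachable connectance/ratio combinations raise a
  configuration error naming the feasible range.
- **Nested**: links fill the upper-left staircase of the degree-sorted
  matrix (pairs `(i, j)` ordered by `i + j`, then `i`) until the budget is
  spent. The construction is deterministic and maximally nested: row
  supports are inclusion-ordered and species 1 is the top generalist.
  Two consequences worth knowing: (a) the result is a *threshold graph*,
  the unique loop-free realization of its degree sequence, so
  degree-preserving swap null models are vacuous on it — nestedness is
  therefore benchmarked against the fixed-fill (shuffled-1s) ensemble;
  (b) at the default connectance the lowest-ranked species are isolated,
  so a directional perturbation aimed at the nested community's
  least-connected species hits nothing (scenario d below) or only that
  species' own growth rate (scenario f).
- **Random**: the budget scattered uniformly — the classic no-structure
  null.

Adjacency is symmetric (presence is mutual) with an all-ones diagonal.
Strengths for each realized off-diagonal entry — `(i, j)` and `(j, i)`
independently — are drawn from Normal(mean 0.15, sd 0.05) truncated to
nonnegative values by resampling; truncation (rather than absolute value
or clipping) keeps the shape of the upper tail and never creates exact
zeros. The defaults make `A` diagonally dominant in expectation
(diagonal 1 against ≈ 6 expected neighbors × 0.15), so generated matrices
are almost always invertible; the realized mean/sd of the nonzero entries
are recorded on each matrix so paired structures can be moment-checked.

Structure metrics: NODF (0–100; pairs of rows/columns with decreasing
fill contribute their paired overlap, computed on the off-diagonal
adjacency) and the within/between module density ratio (∞ returned when
no between-module link exists). Under the defaults, nested NODF ≈ 50
versus modular ≈ 20–25, and the modular contrast ≈ 8.

What the generator does *not* emulate: empirical degree distributions,
asymmetric or signed interactions, bipartite mutualistic structure, or
any dependence of topology on the environment. Passing tests show the
method behaves correctly on communities with these idealized structures,
not that real communities behave like them.

## Initialization and perturbation experiment

Each replicate draws fresh paired topologies and strengths, then one
lognormal abundance vector `N*` (meanlog 0, sdlog 1 — a standard
right-skewed abundance distribution) **shared by both structures**, and
sets `r = A N*` per structure. Sharing the identical abundance vector
(not merely the same distribution) is the strongest controlled
comparison: all between-structure differences within a replicate are
attributable to the interaction arrangement.

Six scenarios, labelled a–f: (a) random noise on all realized interaction
strengths; (b) random noise on all growth rates; (c)/(d) noise on the
most-/least-connected species' column of `A`; (e)/(f) noise on the
most-/least-connected species' growth rate. Noise is additive zero-mean
Gaussian with sd = `magnitude` × the empirical sd of the unperturbed
target entries (default magnitude 0.5). Structural zeros and the diagonal
are never perturbed — perturbing zeros would rewire the network and
conflate structural change with parameter change. Interaction entries
pushed below zero are clamped at 0 and the clamping events counted
(silently flipping competition to facilitation would change the model).
Directional interaction perturbations act on the focal species' *column*
(its per-capita effects as seen by the feasibility-cone basis); ties in
connectedness break to the lowest species index.

Randomness is fanned out from one master seed through keyed streams
`(master, replicate, stream-id)` (numpy `SeedSequence`), with one stream
per stage and per scenario; both structures consume the *same*
perturbation stream of a replicate, and adding scenarios never shifts the
randomness of existing ones. Replicates whose community draw is
degenerate are resampled with fresh keys (counted; an error is raised
after 100 consecutive failures).

Default problem sizes: 5,000 replicates per scenario for the headline
table (≈ 60,000 21×21 linear solves, well under a minute); the
rank-reversal significance check is run at 1,000 replicates with a
two-proportion z-test at p < 0.01.

## Cone geometry and Γ

Γ is estimated as the fraction of draws from Ξ that are feasible — the
Ξ-probability mass inside `D_F(A)`. For a uniform Ξ this is the literal
volume ratio `vol(D_F ∩ Ξ)/vol(Ξ)`; the mass reading generalizes it to
the Gaussian and point-mass families also provided. Estimation is plain
Monte Carlo with binomial standard errors; no quadrature or importance
sampling is attempted because the default dimension is 21. The relative
cone size is the fraction of uniformly random unit directions inside the
cone (2⁻ⁿ for the identity matrix).

The LP membership oracle (`linprog`/HiGHS: find combination coefficients
≥ margin with `basis · x = r`) exists to cross-check the matrix-inverse
feasibility test by an independent route on small instances (n ≤ 6). Its
positivity margin defaults to 1e-6, above the solver's own feasibility
tolerance (≈ 1e-7); a smaller margin would let exact boundary points pass.
Agreement tests exclude instances with condition number > 1e6 or any
equilibrium component within 1e-6 of zero, where the two routes may
legitimately disagree by round-off.

The two-species worked pair used in tests and the `fixtures` CLI: a wide
cone near the positive orthant (`[[1, 0.1], [0.1, 1]]`, ≈ 78.6° wide) and
a narrow cone tilted below it (`[[1, 0.6], [−0.4, 0.25]]`, ≈ 44.4° wide),
with Ξ a tight Gaussian centred inside the narrow cone only. The narrow
cone's Γ exceeds the wide one's by three orders of standard error —
the overlap, not the cone size, is what predicts persistence.

## Known limitations

- No time integration: transient extinctions along the path to the new
  equilibrium are invisible to the feasibility criterion.
- Competition only; the clamping convention means very large perturbation
  magnitudes pile probability mass at zero interaction strength.
- The environment families (Gaussian, uniform box, point mass) are
  parametric stand-ins; mapping real climate variables to growth rates or
  carrying capacities is out of scope.
- Panel-by-panel orderings of the persistence table depend on the
  defaults documented here (connectance, ratio, magnitude, lognormal
  spread); only the existence of a rank reversal is treated as a stable
  claim.
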