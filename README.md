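# ecofeas

Feasibility-domain analysis of ecological interaction networks under
generalized Lotka–Volterra dynamics.

## The problem

Community ecologists have long tried to rank network structures — modular
("cliquish") versus nested ("specialists interact with subsets of
generalists' partners") — by how well communities built on them tolerate
external perturbations. `ecofeas` is a pipeline for running that comparison
cleanly, and for showing why its answer is perturbation-dependent: which
structure looks "more robust" flips with the type, target, and direction of
the perturbation. The constructive alternative it implements is an
environment-dependent overlap statistic, Γ, between a community's
feasibility domain and a distribution of environmental conditions.

## The model

Dynamics are the Lotka–Volterra competition system

    dN/dt = N ∘ (r − A N)

with abundances `N`, intrinsic growth rates `r` (the environment-dependent
parameters), and interaction matrix `A` (nonnegative entries, positive
diagonal). The interior equilibrium is `N* = A⁻¹ r`; a community is
**feasible** — persists with no extinctions — iff `N* > 0` componentwise.
Geometrically, the set of growth-rate vectors satisfying this is the
**feasibility domain**

    D_F(A) = { r = N₁* v₁ + … + Nₙ* vₙ : all Nᵢ* > 0 },

the open cone spanned by the columns `vᵢ` of `A`. Given an environment
distribution Ξ over growth-rate space, the overlap

    Γ(D_F(A) ∩ Ξ) = vol(D_F(A) ∩ Ξ) / vol(Ξ)

(the Ξ-probability mass inside the cone; the literal volume ratio when Ξ is
uniform) measures how much of the locally expected environment the
structure can tolerate. A structure with a *smaller* cone can still score a
*larger* Γ when the environment happens to sit inside its cone — cone size
alone ranks nothing.

The perturbation experiment builds, per replicate, a matched pair of
21-species communities (modular and nested; same link budget, same
strength distribution with matched mean and sd, same lognormal abundance
vector `N*`), initializes both inside their feasibility domains via
`r = A N*`, applies one of six perturbation scenarios — random or
directional (most-/least-connected species), on interactions or growth
rates — and records whether the perturbed community is still feasible,
5,000 times per scenario.

## Worked example

```python
from ecofeas import ExperimentConfig, run_persistence_experiment

table = run_persistence_experiment(ExperimentConfig(n_reps=1000, seed=0))
df = table.to_frame()
print(df.pivot(index="scenario", columns="structure", values="persisted_count"))
```

prints

```
structure  modular  nested
scenario
a              694     679
b               32      16
c              982     965
d              993    1000
e              742     628
f              792     807
```

Each cell is the number of replicates (out of 1,000) in which that
structure tolerated the perturbation with no extinction. Scenario `e`
(directional growth-rate perturbation of the most-connected species)
significantly favors the modular community (742 vs 628), while scenario
`d` (directional interaction perturbation of the least-connected species)
significantly favors the nested one (993 vs 1000) — the ranking of
structures reverses across scenarios, which is the point. (The nested
community's least-connected species is isolated at the default
connectance, so scenario `d` cannot harm it at all.)

The same flip appears in the Γ statistic. A two-species worked geometry:

```bash
ecofeas fixtures --out fixtures/ --seed 0
# two-species fixture: gamma(wide) = 0.067, gamma(narrow) = 0.999
```

The wide cone covers 21.7% of all growth-rate directions and the narrow
one only 3.6%, yet the environment (a Gaussian Ξ centred inside the narrow
cone) overlaps the narrow cone almost completely: Γ_narrow ≈ 0.999 versus
Γ_wide ≈ 0.067.

Other entry points: `ecofeas generate` (topologies and matrices as CSV),
`ecofeas experiment` (the persistence table, YAML-configurable), and
`ecofeas gamma` (Γ for a matrix CSV and an environment spec).

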