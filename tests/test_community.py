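"""Topology generators, strength assignment, and structure metrics."""

import math

import numpy as np
import pytest

from ecofeas import (
    ConfigurationError,
    StrengthSpec,
    StructureSpec,
    assign_interaction_strengths,
    generate_modular_topology,
    generate_nested_topology,
    generate_random_topology,
    generate_topology,
    modularity_contrast,
    nestedness_nodf,
    nodf,
)
from ecofeas.community import (
    BinaryTopology,
    is_nested_by_inclusion,
    target_link_pairs,
)

STRUCTURES = ["modular", "nested", "random"]


@pytest.mark.parametrize("structure", STRUCTURES)
def test_generators_are_deterministic(structure, default_specs):
    a = generate_topology(default_specs(structure, seed=7))
    b = generate_topology(default_specs(structure, seed=7))
    assert np.array_equal(a.adjacency, b.adjacency)


@pytest.mark.parametrize("structure", STRUCTURES)
def test_default_topology_shape_and_diagonal(structure, default_specs):
    topo = generate_topology(default_specs(structure))
    assert topo.adjacency.shape == (21, 21)
    assert np.all(np.diag(topo.adjacency) == 1)
    assert np.array_equal(topo.adjacency, topo.adjacency.T)
    assert set(np.unique(topo.adjacency)) <= {0, 1}


def test_link_budget_matched_across_structures(default_specs):
    """Paired structures differ in arrangement, never in link count."""
    counts = {
        s: generate_topology(default_specs(s, seed=3)).n_links() for s in STRUCTURES
    }
    assert len(set(counts.values())) == 1
    assert counts["modular"] == target_link_pairs(21, 0.3)


def test_realized_connectance_near_target(default_specs):
    topo = generate_topology(default_specs("modular"))
    realized = topo.n_links() / (21 * 20 / 2)
    assert abs(realized - 0.3) <= 1 / (21 * 20 / 2)


def test_extreme_probabilities_force_block_diagonal():
    """within-p=1, between-p=0 yields two complete 3-species blocks."""
    spec = StructureSpec(
        n=6, structure="modular", n_modules=2, connectance=0.4,
        within_between_ratio=math.inf, seed=0,
    )
    topo = generate_modular_topology(spec)
    block = np.ones((3, 3), dtype=int)
    expected = np.zeros((6, 6), dtype=int)
    expected[:3, :3] = block
    expected[3:, 3:] = block
    assert np.array_equal(topo.adjacency, expected)
    assert modularity_contrast(topo) == math.inf


def test_modular_configuration_errors():
    with pytest.raises(ConfigurationError, match="divisible"):
        StructureSpec(n=21, structure="modular", n_modules=4)
    spec = StructureSpec(
        n=6, structure="modular", n_modules=2, connectance=0.9,
        within_between_ratio=math.inf,
    )
    with pytest.raises(ConfigurationError, match="feasible connectance"):
        generate_modular_topology(spec)
    with pytest.raises(ConfigurationError, match="connectance"):
        StructureSpec(structure="nested", connectance=0.0)


def test_nested_small_example():
    """n=3, two links: the generalist pairs with both specialists."""
    spec = StructureSpec(n=3, structure="nested", connectance=2 / 3)
    topo = generate_nested_topology(spec)
    supports = [set(np.flatnonzero(topo.offdiag()[i])) for i in range(3)]
    assert supports == [{1, 2}, {0}, {0}]


def test_nested_supports_are_inclusion_ordered(default_specs):
    topo = generate_nested_topology(default_specs("nested"))
    assert is_nested_by_inclusion(topo)
    deg = topo.degrees()
    assert np.all(np.diff(deg) <= 0)  # generalists first


def test_random_generator_varies_with_seed(default_specs):
    differing = 0
    for seed in range(10):
        a = generate_random_topology(default_specs("random", seed=seed))
        b = generate_random_topology(default_specs("random", seed=seed + 100))
        differing += not np.array_equal(a.adjacency, b.adjacency)
    assert differing >= 1


def test_complete_matrix_at_full_connectance():
    spec = StructureSpec(n=5, structure="random", connectance=1.0)
    topo = generate_random_topology(spec)
    assert np.array_equal(topo.adjacency, np.ones((5, 5), dtype=int))


# ---------------------------------------------------------------------------
# interaction strengths
# ---------------------------------------------------------------------------


def test_empty_topology_gives_diagonal_matrix():
    topo = BinaryTopology(adjacency=np.eye(4, dtype=int), structure_label="random")
    mat = assign_interaction_strengths(topo, StrengthSpec(diag_value=2.5))
    assert np.array_equal(mat.A, 2.5 * np.eye(4))
    assert mat.realized_mean is None


def test_zero_spread_gives_constant_strengths(default_specs):
    topo = generate_topology(default_specs("modular"))
    mat = assign_interaction_strengths(topo, StrengthSpec(mean=0.2, sd=0.0))
    off = topo.offdiag().astype(bool)
    assert np.all(mat.A[off] == 0.2)
    assert np.all(mat.A[~off & ~np.eye(21, dtype=bool)] == 0.0)


def test_strengths_preserve_zeros_and_are_nonnegative(default_specs):
    topo = generate_topology(default_specs("nested"))
    mat = assign_interaction_strengths(topo, StrengthSpec(mean=0.01, sd=0.5, seed=1))
    off = topo.offdiag().astype(bool)
    assert np.all(mat.A[off] >= 0)  # truncated at 0 (competition only)
    assert np.all(mat.A[off] > 0)  # resampling, not clipping to exact zero
    zeros = ~off & ~np.eye(21, dtype=bool)
    assert np.all(mat.A[zeros] == 0.0)
    assert np.all(np.diag(mat.A) == 1.0)


def test_paired_structures_are_moment_matched(default_specs, default_strengths):
    """Mean and sd of nonzero strengths agree across structures (10 seeds)."""
    dmean, dsd = [], []
    for seed in range(10):
        mats = {
            s: assign_interaction_strengths(
                generate_topology(default_specs(s, seed=seed)),
                default_strengths,
                seed=seed,
            )
            for s in ("modular", "nested")
        }
        dmean.append(mats["modular"].realized_mean - mats["nested"].realized_mean)
        dsd.append(mats["modular"].realized_sd - mats["nested"].realized_sd)
    assert abs(np.mean(dmean)) < 1e-2
    assert abs(np.mean(dsd)) < 1e-2


def test_strength_spec_validation():
    with pytest.raises(ConfigurationError):
        StrengthSpec(sd=-0.1)
    with pytest.raises(ConfigurationError):
        StrengthSpec(diag_value=0.0)


# ---------------------------------------------------------------------------
# structure metrics
# ---------------------------------------------------------------------------


def test_nodf_perfect_staircase_is_100():
    M = np.array(
        [[1, 1, 1, 1], [1, 1, 1, 0], [1, 1, 0, 0], [1, 0, 0, 0]]
    )
    assert nodf(M) == pytest.approx(100.0)


def test_nodf_equal_degrees_is_0():
    assert nodf(np.array([[1, 0], [0, 1]])) == 0.0
    assert nodf(np.ones((3, 3))) == 0.0


def test_structural_separation_over_seeds(default_specs):
    """Nested beats modular on NODF and modular beats nested on contrast,
    in every one of 20 default-config replicates."""
    for seed in range(20):
        tm = generate_topology(default_specs("modular", seed=seed))
        tn = generate_topology(default_specs("nested", seed=seed))
        assert nestedness_nodf(tn) > nestedness_nodf(tm)
        assert modularity_contrast(tm) > 1.0
        # nested topology has no partition; impose the modular one on it
        tn_part = BinaryTopology(
            adjacency=tn.adjacency,
            structure_label="modular",
            module_partition=tm.module_partition,
        )
        assert modularity_contrast(tm) > modularity_contrast(tn_part)


def test_nested_nodf_beats_link_shuffled_null(default_specs):
    """The nested generator scores higher than 100 random rearrangements of
    the same 1s (the classic fixed-fill null ensemble)."""
    topo = generate_nested_topology(default_specs("nested"))
    score = nestedness_nodf(topo)
    rng = np.random.default_rng(123)
    n, L = topo.n, topo.n_links()
    iu = np.column_stack(np.triu_indices(n, k=1))
    for _ in range(100):
        chosen = iu[rng.choice(len(iu), size=L, replace=False)]
        shuffled = np.zeros((n, n), dtype=int)
        shuffled[chosen[:, 0], chosen[:, 1]] = 1
        shuffled += shuffled.T
        assert score > nodf(shuffled)


def test_perfect_fill_is_rigid_under_degree_preserving_swaps(default_specs):
    """The maximally nested fill is a threshold graph: no degree-preserving
    edge swap exists, so the degree sequence pins the topology uniquely."""
    off = generate_nested_topology(default_specs("nested")).offdiag()
    edges = np.argwhere(np.triu(off, 1))
    for u, v in edges:
        for x, y in edges:
            for a, b in ((x, y), (y, x)):
                if len({u, v, a, b}) == 4 and not off[u, a] and not off[v, b]:
                    pytest.fail(f"valid swap found: ({u},{v}),({a},{b})")


def test_modularity_contrast_uniform_random_is_near_one(default_specs):
    ratios = []
    for seed in range(50):
        topo = generate_random_topology(default_specs("random", seed=seed))
        with_part = BinaryTopology(
            adjacency=topo.adjacency,
            structure_label="modular",
            module_partition=np.repeat(np.arange(3), 7),
        )
        ratios.append(modularity_contrast(with_part))
    se = np.std(ratios, ddof=1) / np.sqrt(len(ratios))
    assert abs(np.mean(ratios) - 1.0) < 3 * se + 0.05


def test_modularity_contrast_requires_partition(default_specs):
    topo = generate_nested_topology(default_specs("nested"))
    with pytest.raises(ValueError, match="partition"):
        modularity_contrast(topo)
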