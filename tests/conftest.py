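import numpy as np
import pytest

from ecofeas import StrengthSpec, StructureSpec


@pytest.fixture
def default_specs():
    """Paired default structure specs (21 species, shared link budget)."""

    def make(structure: str, seed: int = 0) -> StructureSpec:
        return StructureSpec(structure=structure, seed=seed)

    return make


@pytest.fixture
def default_strengths():
    return StrengthSpec()


def random_conditioned_matrix(rng, n, cond_max=1e6):
    """A random matrix with bounded condition number (rejection sampled)."""
    while True:
        A = rng.normal(size=(n, n))
        if np.linalg.cond(A) <= cond_max:
            return A
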