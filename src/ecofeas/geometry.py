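"""Feasibility-cone geometry and the environment-overlap statistic Γ.

The feasibility domain D_F(A) of an LV community is the open cone

    D_F(A) = { r = N1* v1 + ... + Nn* vn : N1* > 0, ..., Nn* > 0 }

spanned by the columns v_i of the interaction matrix A: the set of
growth-rate vectors compatible with all species coexisting.  Because the
growth rates are the environment-dependent parameters, the overlap

    Γ(D_F(A) ∩ Ξ) = mass of the environment distribution Ξ inside D_F(A)

measures how much of the locally expected environment a given network
structure can tolerate.  For a uniform Ξ this is the literal volume ratio
vol(D_F ∩ Ξ)/vol(Ξ); for a general Ξ it is the probability that a drawn
environment is feasible.  Both Γ and the relative cone size are estimated
by Monte Carlo (the default community size, 21, rules out quadrature).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .lv import InteractionMatrix, _as_array, equilibrium_abundances

__all__ = [
    "FeasibilityCone",
    "EnvironmentDistribution",
    "GammaEstimate",
    "BOUNDARY_TOL",
    "cone_membership_oracle",
    "cone_border_angles_2d",
    "sample_environment",
    "estimate_gamma",
    "relative_cone_size",
]

#: Draws with any equilibrium component closer to 0 than this count as
#: outside the (open) cone.
BOUNDARY_TOL = 1e-12

#: The LP membership oracle is a testing device; refuse silly dimensions.
ORACLE_MAX_DIM = 6


@dataclass
class FeasibilityCone:
    """The cone of strictly positive combinations of a basis (columns of A)."""

    basis: np.ndarray  # shape (n, n); column i is v_i

    def __post_init__(self) -> None:
        self.basis = np.asarray(self.basis, dtype=float)
        if self.basis.ndim != 2:
            raise ValueError("basis must be a 2-D array of column vectors")
        if not np.all(np.isfinite(self.basis)):
            raise ValueError("basis contains non-finite entries")

    @classmethod
    def from_interaction_matrix(cls, A) -> "FeasibilityCone":
        return cls(basis=_as_array(A).copy())

    @property
    def n(self) -> int:
        return self.basis.shape[0]


@dataclass
class EnvironmentDistribution:
    """Parametric environment Ξ: a sampleable distribution over growth-rate
    space.

    Three families are provided: ``gaussian`` (mean + covariance),
    ``uniform_box`` (axis-aligned box, the literal volume-ratio reading of
    Γ), and ``point_mass`` (a single environmental condition).
    """

    kind: str
    n: int
    mean: np.ndarray | None = None
    cov: np.ndarray | None = None
    low: np.ndarray | None = None
    high: np.ndarray | None = None
    location: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "uniform_box", "point_mass"):
            raise ValueError(f"unknown environment kind {self.kind!r}")
        if self.kind == "gaussian":
            self.mean = np.asarray(self.mean, dtype=float)
            self.cov = np.asarray(self.cov, dtype=float)
            if self.mean.shape != (self.n,) or self.cov.shape != (self.n, self.n):
                raise ValueError("gaussian needs mean (n,) and cov (n, n)")
            if not np.allclose(self.cov, self.cov.T):
                raise ValueError("covariance must be symmetric")
            if np.any(np.linalg.eigvalsh(self.cov) < -1e-10):
                raise ValueError("covariance must be positive semidefinite")
        elif self.kind == "uniform_box":
            self.low = np.asarray(self.low, dtype=float)
            self.high = np.asarray(self.high, dtype=float)
            if self.low.shape != (self.n,) or self.high.shape != (self.n,):
                raise ValueError("uniform_box needs low and high of shape (n,)")
            if np.any(self.high < self.low):
                raise ValueError("box corners must satisfy low <= high")
        else:
            self.location = np.asarray(self.location, dtype=float)
            if self.location.shape != (self.n,):
                raise ValueError("point_mass needs a location of shape (n,)")

    @classmethod
    def gaussian(cls, mean, cov) -> "EnvironmentDistribution":
        mean = np.asarray(mean, dtype=float)
        return cls(kind="gaussian", n=mean.shape[0], mean=mean, cov=cov)

    @classmethod
    def uniform_box(cls, low, high) -> "EnvironmentDistribution":
        low = np.asarray(low, dtype=float)
        return cls(kind="uniform_box", n=low.shape[0], low=low, high=high)

    @classmethod
    def point_mass(cls, location) -> "EnvironmentDistribution":
        location = np.asarray(location, dtype=float)
        return cls(kind="point_mass", n=location.shape[0], location=location)


@dataclass(frozen=True)
class GammaEstimate:
    """Monte Carlo estimate of Γ with its binomial standard error."""

    gamma: float
    se: float
    n_samples: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError("gamma must lie in [0, 1]")


def cone_membership_oracle(
    cone: FeasibilityCone,
    r: np.ndarray,
    *,
    margin: float = 1e-6,
    max_dim: int = ORACLE_MAX_DIM,
) -> bool:
    """Decide cone membership by linear-program feasibility, not inversion.

    Membership of r in the open cone is certified by finding coefficients
    x >= margin with  basis @ x = r.  This is an independent cross-check
    for :func:`ecofeas.lv.is_feasible` on small instances; points within
    ``margin`` of the boundary are rejected (strict positivity).  The
    margin must sit above the LP solver's own primal feasibility tolerance
    (~1e-7 for HiGHS), otherwise boundary points are accepted.
    """
    r = np.asarray(r, dtype=float)
    if cone.n > max_dim:
        raise ValueError(
            f"membership oracle is a small-instance testing device (n <= {max_dim})"
        )
    if r.shape != (cone.n,):
        raise ValueError(f"r has shape {r.shape}, expected ({cone.n},)")
    res = linprog(
        c=np.zeros(cone.basis.shape[1]),
        A_eq=cone.basis,
        b_eq=r,
        bounds=[(margin, None)] * cone.basis.shape[1],
        method="highs",
    )
    return bool(res.status == 0)


def cone_border_angles_2d(cone: FeasibilityCone) -> tuple[float, float]:
    """Polar angles of the two borders of a 2-D cone.

    Returns ``(angle_low, angle_high)`` such that the cone is swept
    counter-clockwise from low to high within a half-turn; membership by
    angle agrees with the LP oracle.  Antiparallel or parallel basis
    vectors do not bound a proper (salient, full-dimensional) cone and
    raise ``ValueError``.
    """
    if cone.n != 2 or cone.basis.shape != (2, 2):
        raise ValueError("cone_border_angles_2d requires a 2-D cone")
    v1, v2 = cone.basis[:, 0], cone.basis[:, 1]
    if np.linalg.norm(v1) == 0 or np.linalg.norm(v2) == 0:
        raise ValueError("degenerate basis: zero column")
    cross = v1[0] * v2[1] - v1[1] * v2[0]
    if abs(cross) < 1e-12 * np.linalg.norm(v1) * np.linalg.norm(v2):
        raise ValueError("degenerate basis: columns are (anti)parallel")
    a1 = math.atan2(v1[1], v1[0])
    a2 = math.atan2(v2[1], v2[0])
    d = (a2 - a1) % (2 * math.pi)
    if d < math.pi:
        return a1, a1 + d
    return a2, a2 + (2 * math.pi - d)


def sample_environment(
    xi: EnvironmentDistribution, n_samples: int, seed=None
) -> np.ndarray:
    """Draw ``n_samples`` growth-rate vectors from Ξ; shape (n_samples, n)."""
    if n_samples < 1:
        raise ValueError("n_samples must be positive")
    rng = np.random.default_rng(seed)
    if xi.kind == "point_mass":
        return np.tile(xi.location, (n_samples, 1))
    if xi.kind == "uniform_box":
        return rng.uniform(xi.low, xi.high, size=(n_samples, xi.n))
    return rng.multivariate_normal(
        xi.mean, xi.cov, size=n_samples, method="svd"
    )


def _inside_cone_batch(A: np.ndarray, R: np.ndarray, tol: float) -> np.ndarray:
    """Boolean mask: which rows of R are strictly inside D_F(A)."""
    X = np.linalg.solve(A, R.T)  # (n, n_samples) of equilibrium abundances
    return np.all(X > tol, axis=0)


def estimate_gamma(
    A,
    xi: EnvironmentDistribution,
    n_samples: int = 10_000,
    seed=None,
    *,
    boundary_tol: float = BOUNDARY_TOL,
) -> GammaEstimate:
    """Monte Carlo estimate of Γ(D_F(A) ∩ Ξ): the Ξ-mass inside the cone.

    gamma is the fraction of draws r ~ Ξ whose equilibrium A^-1 r is
    componentwise strictly positive; draws within ``boundary_tol`` of the
    boundary count as outside.  se is the binomial standard error
    sqrt(gamma(1-gamma)/n_samples).  Deterministic given ``seed``.
    """
    Aarr = _as_array(A)
    if Aarr.shape[0] != xi.n:
        raise ValueError("matrix and environment dimensions differ")
    # raises DegenerateMatrixError on unusable A
    equilibrium_abundances(Aarr, np.zeros(Aarr.shape[0]))
    R = sample_environment(xi, n_samples, seed)
    inside = _inside_cone_batch(Aarr, R, boundary_tol)
    gamma = float(inside.mean())
    se = math.sqrt(gamma * (1.0 - gamma) / n_samples)
    return GammaEstimate(
        gamma=gamma,
        se=se,
        n_samples=n_samples,
        seed=seed if isinstance(seed, int) else None,
    )


def relative_cone_size(
    A,
    n_samples: int = 10_000,
    seed=None,
    *,
    boundary_tol: float = BOUNDARY_TOL,
) -> GammaEstimate:
    """Fraction of the unit sphere of growth-rate directions inside D_F(A).

    Directions are drawn uniformly (normalized Gaussians).  The identity
    matrix spans the positive orthant, giving 2^-n in the large-sample
    limit.  The estimate is invariant under positive rescaling of A's
    columns, which leaves the cone unchanged.
    """
    Aarr = _as_array(A)
    equilibrium_abundances(Aarr, np.zeros(Aarr.shape[0]))
    rng = np.random.default_rng(seed)
    D = rng.standard_normal((n_samples, Aarr.shape[0]))
    D /= np.linalg.norm(D, axis=1, keepdims=True)
    inside = _inside_cone_batch(Aarr, D, boundary_tol)
    frac = float(inside.mean())
    se = math.sqrt(frac * (1.0 - frac) / n_samples)
    return GammaEstimate(
        gamma=frac,
        se=se,
        n_samples=n_samples,
        seed=seed if isinstance(seed, int) else None,
    )
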