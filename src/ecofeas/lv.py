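"""Lotka-Volterra equilibrium, feasibility, and feasible initialization.

The community model is the generalized Lotka-Volterra competition system

    dN/dt = N * (r - A N)

with abundances ``N`` (length-n, positive), intrinsic growth rates ``r``
(the environment-dependent parameters), and interaction matrix ``A``
(positive entries = competitive per-capita effects, positive diagonal =
self-regulation).  The interior equilibrium is ``N* = A^-1 r``; the
community is *feasible* — no species extinct at equilibrium — iff every
component of ``N*`` is strictly positive.

Communities are initialized *inside* the feasibility domain by fixing a
lognormal abundance vector ``N*`` and back-solving ``r = A N*``, so the
starting point is feasible by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InteractionMatrix",
    "DegenerateMatrixError",
    "DEFAULT_COND_BOUND",
    "equilibrium_abundances",
    "is_feasible",
    "sample_lognormal_abundances",
    "initialize_feasible_community",
]

#: Condition-number estimate above which a matrix is declared degenerate.
DEFAULT_COND_BOUND = 1e12


class DegenerateMatrixError(ValueError):
    """Raised when an interaction matrix is singular or too ill-conditioned
    to define a usable equilibrium.  Carries the condition estimate so
    callers (e.g. the perturbation experiment) can log and resample."""

    def __init__(self, cond: float):
        self.cond = float(cond)
        super().__init__(
            f"interaction matrix is degenerate (condition estimate {cond:.3e}); "
            "resample the community or relax the bound"
        )


@dataclass
class InteractionMatrix:
    """Quantitative interaction network: the n x n matrix A of the LV model.

    Columns of ``A`` span the feasibility cone.  ``structure_label`` is a
    provenance tag (modular / nested / random / "").  ``realized_mean`` and
    ``realized_sd`` are the moments of the nonzero off-diagonal entries,
    recorded at generation time so paired structures can be moment-checked.
    """

    A: np.ndarray
    structure_label: str = ""
    realized_mean: float | None = None
    realized_sd: float | None = None
    species_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim != 2 or self.A.shape[0] != self.A.shape[1]:
            raise ValueError(f"A must be square, got shape {self.A.shape}")
        if not np.all(np.isfinite(self.A)):
            raise ValueError("A contains non-finite entries")
        if np.any(np.diag(self.A) <= 0):
            raise ValueError("diagonal (self-regulation) must be strictly positive")
        if not self.species_ids:
            self.species_ids = [f"S{i + 1}" for i in range(self.A.shape[0])]
        elif len(self.species_ids) != self.A.shape[0]:
            raise ValueError("species_ids length does not match matrix size")

    @property
    def n(self) -> int:
        return self.A.shape[0]


def _as_array(A) -> np.ndarray:
    if isinstance(A, InteractionMatrix):
        return A.A
    return np.asarray(A, dtype=float)


def _check_condition(A: np.ndarray, cond_bound: float | None) -> None:
    if cond_bound is None:
        return
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > cond_bound:
        raise DegenerateMatrixError(cond)


def equilibrium_abundances(
    A,
    r: np.ndarray,
    *,
    cond_bound: float | None = DEFAULT_COND_BOUND,
    rtol: float = 1e-8,
) -> np.ndarray:
    """Solve A N* = r for the interior equilibrium N*.

    Raises :class:`DegenerateMatrixError` when the condition estimate of A
    exceeds ``cond_bound`` (default 1e12) or the residual check fails.
    """
    Aarr = _as_array(A)
    r = np.asarray(r, dtype=float)
    if r.shape != (Aarr.shape[0],):
        raise ValueError(f"growth-rate vector has shape {r.shape}, expected ({Aarr.shape[0]},)")
    _check_condition(Aarr, cond_bound)
    try:
        nstar = np.linalg.solve(Aarr, r)
    except np.linalg.LinAlgError:
        raise DegenerateMatrixError(np.inf) from None
    resid = np.linalg.norm(Aarr @ nstar - r)
    if resid > rtol * max(np.linalg.norm(r), 1.0):
        raise DegenerateMatrixError(np.linalg.cond(Aarr))
    return nstar


def is_feasible(
    A,
    r: np.ndarray,
    *,
    eps_pos: float = 0.0,
    cond_bound: float | None = DEFAULT_COND_BOUND,
) -> bool:
    """True iff every equilibrium abundance A^-1 r is strictly above ``eps_pos``.

    This is the membership test for the feasibility domain D_F(A): the cone
    of growth-rate vectors expressible as strictly positive combinations of
    the columns of A.  Strict inequality implements the open cone; the
    threshold is exposed to study numerical borderline cases.
    """
    nstar = equilibrium_abundances(A, r, cond_bound=cond_bound)
    return bool(np.all(nstar > eps_pos))


def _feasible_fast(A: np.ndarray, r: np.ndarray, eps_pos: float = 0.0) -> bool:
    # hot-loop variant: no condition estimate, singular solve -> infeasible
    try:
        return bool(np.all(np.linalg.solve(A, r) > eps_pos))
    except np.linalg.LinAlgError:
        return False


def sample_lognormal_abundances(
    n: int,
    meanlog: float = 0.0,
    sdlog: float = 1.0,
    seed=None,
) -> np.ndarray:
    """Draw n independent lognormal abundances (all strictly positive).

    ``meanlog``/``sdlog`` parameterize the underlying normal on the log
    scale.  ``seed`` may be an int, a SeedSequence, or a Generator.
    """
    if sdlog < 0:
        raise ValueError("sdlog must be nonnegative")
    if n < 1:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    return rng.lognormal(mean=meanlog, sigma=sdlog, size=n)


def initialize_feasible_community(
    A,
    meanlog: float = 0.0,
    sdlog: float = 1.0,
    seed=None,
    *,
    cond_bound: float | None = DEFAULT_COND_BOUND,
) -> tuple[np.ndarray, np.ndarray]:
    """Initialize inside the feasibility domain: draw lognormal N* and set r = A N*.

    Returns ``(r, N*)``.  Feasibility of (A, r) holds by construction up to
    round-off: r is literally a positive combination of A's columns.
    """
    Aarr = _as_array(A)
    _check_condition(Aarr, cond_bound)
    nstar = sample_lognormal_abundances(Aarr.shape[0], meanlog, sdlog, seed)
    r = Aarr @ nstar
    return r, nstar
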