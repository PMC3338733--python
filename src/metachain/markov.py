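"""Row-stochastic transition matrices, state propagation and stationarity.

Conventions
-----------
States are row vectors and act on the left: one step of the chain is
``v_{k+1} = v_k @ A``, where ``A[i, j]`` is the probability of stepping
from site ``i`` to site ``j``.  A stationary distribution is therefore a
left eigenvector of ``A`` for eigenvalue 1.  Because every row of ``A``
sums to one, eigenvalue 1 always exists; it need not be simple, in which
case the stationary distribution is not unique and a
:class:`NonUniqueStationaryWarning` is raised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .atlas import SiteAtlas, SiteDistribution

__all__ = [
    "TransitionMatrix",
    "StateTrajectory",
    "MatrixValidationError",
    "NonUniqueStationaryWarning",
    "PowerIterationError",
    "validate",
    "require_valid",
    "propagate",
    "stationary_distribution",
    "evolve_to_convergence",
    "ROW_SUM_TOL",
]

#: absolute tolerance on |row sum - 1| for a valid transition matrix
ROW_SUM_TOL = 1e-9

#: eigenvalues within this distance of 1 count toward the multiplicity of 1
_EIGENVALUE_ONE_TOL = 1e-8


class MatrixValidationError(ValueError):
    """The matrix violates the row-stochastic constraints."""


class PowerIterationError(RuntimeError):
    """Power iteration failed to converge (e.g. a periodic chain)."""


class NonUniqueStationaryWarning(UserWarning):
    """Eigenvalue 1 has multiplicity > 1: the stationary distribution is not unique."""


@dataclass(frozen=True)
class TransitionMatrix:
    """Square row-stochastic matrix of one-step transition probabilities.

    The constructor only checks the shape against the atlas; use
    :func:`validate` / :func:`require_valid` for the stochasticity
    constraints (entries in [0, 1], rows summing to 1).
    """

    atlas: SiteAtlas
    a: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.a, dtype=float).copy()
        arr.setflags(write=False)
        object.__setattr__(self, "a", arr)
        n = self.atlas.n
        if arr.shape != (n, n):
            raise MatrixValidationError(
                f"expected {n}x{n} matrix for this atlas, got shape {arr.shape}"
            )

    def __getitem__(self, key: tuple[int, int]) -> float:
        i, j = key
        return float(self.a[self.atlas.index(i), self.atlas.index(j)])

    def validate(self, tol: float = ROW_SUM_TOL) -> list[str]:
        return validate(self, tol)


def validate(M: TransitionMatrix, tol: float = ROW_SUM_TOL) -> list[str]:
    """Return a list of human-readable constraint violations (empty if valid).

    Checks every entry lies in [0, 1] and every row sums to 1 within ``tol``.
    Row/column positions in messages are 1-based site ids.
    """
    violations: list[str] = []
    a = M.a
    neg = np.argwhere(a < -0.0)
    for i, j in neg:
        violations.append(f"negative entry at ({i + 1}, {j + 1}): {a[i, j]!r}")
    over = np.argwhere(a > 1.0)
    for i, j in over:
        violations.append(f"entry > 1 at ({i + 1}, {j + 1}): {a[i, j]!r}")
    sums = a.sum(axis=1)
    for i in np.nonzero(np.abs(sums - 1.0) > tol)[0]:
        violations.append(f"row {i + 1} sums to {sums[i]!r}, not 1")
    return violations


def require_valid(M: TransitionMatrix, tol: float = ROW_SUM_TOL) -> None:
    violations = validate(M, tol)
    if violations:
        raise MatrixValidationError("; ".join(violations[:5]))


def propagate(v: SiteDistribution, M: TransitionMatrix, k: int = 1) -> SiteDistribution:
    """Advance a state vector ``k`` steps: returns ``v @ M^k``.

    Probability mass is conserved exactly up to floating point; the result
    is renormalized to guard against drift over many steps.
    """
    if v.atlas is not M.atlas and v.atlas != M.atlas:
        raise ValueError("state vector and matrix must share an atlas")
    if k < 0:
        raise ValueError(f"step count must be >= 0, got {k}")
    p = v.p.copy()
    for _ in range(int(k)):
        p = p @ M.a
    return SiteDistribution.renormalized(M.atlas, p)


def _power_iteration(
    a: np.ndarray,
    start: np.ndarray,
    tol: float = 1e-12,
    max_iter: int = 100_000,
) -> np.ndarray:
    """Left power iteration ``v <- vA`` until the L1 step change < tol."""
    v = start / start.sum()
    for _ in range(max_iter):
        v2 = v @ a
        v2 /= v2.sum()
        if np.abs(v2 - v).sum() < tol:
            return v2
        v = v2
    raise PowerIterationError(
        f"power iteration did not converge within {max_iter} iterations "
        "(the chain may be periodic)"
    )


def _eigenvalue_one_multiplicity(a: np.ndarray) -> int:
    eigvals = scipy.linalg.eigvals(a)
    return int(np.sum(np.abs(eigvals - 1.0) < _EIGENVALUE_ONE_TOL))


def stationary_distribution(
    M: TransitionMatrix, method: str = "eigen"
) -> SiteDistribution:
    """Stationary distribution pi with ``pi @ A = pi``, ``pi >= 0``, ``sum(pi) = 1``.

    Parameters
    ----------
    M
        A valid transition matrix.
    method
        ``"eigen"`` extracts the left eigenvector for the eigenvalue nearest
        1 (entrywise absolute value, renormalized, since numerical
        eigenvectors are defined up to sign/scale).  ``"power"`` iterates
        ``v <- vA`` from the uniform distribution to absolute L1 tolerance
        1e-12.  The two agree to high accuracy when eigenvalue 1 is simple.

    Warns
    -----
    NonUniqueStationaryWarning
        If eigenvalue 1 has multiplicity > 1 (or the eigenvector has
        genuinely mixed signs).  The power-iteration result from the
        uniform start is then returned, which is one valid stationary
        distribution among many.
    """
    require_valid(M)
    if method not in ("power", "eigen"):
        raise ValueError(f"method must be 'power' or 'eigen', got {method!r}")
    a = M.a
    n = M.atlas.n

    multiplicity = _eigenvalue_one_multiplicity(a)
    if multiplicity > 1:
        warnings.warn(
            f"eigenvalue 1 has multiplicity {multiplicity}; returning the "
            "power-iteration stationary distribution from the uniform start",
            NonUniqueStationaryWarning,
            stacklevel=2,
        )
        pi = _power_iteration(a, np.full(n, 1.0 / n))
        return SiteDistribution.renormalized(M.atlas, pi)

    if method == "power":
        pi = _power_iteration(a, np.full(n, 1.0 / n))
        return SiteDistribution.renormalized(M.atlas, pi)

    eigvals, left = scipy.linalg.eig(a, left=True, right=False)
    idx = int(np.argmin(np.abs(eigvals - 1.0)))
    w = left[:, idx]
    # rotate the numerical phase away, then check sign consistency
    pivot = w[int(np.argmax(np.abs(w)))]
    w = np.real(w * np.conj(pivot) / abs(pivot))
    if np.any(w < -1e-8 * np.abs(w).max()):
        warnings.warn(
            "mixed-sign left eigenvector for eigenvalue 1; returning the "
            "power-iteration stationary distribution from the uniform start",
            NonUniqueStationaryWarning,
            stacklevel=2,
        )
        pi = _power_iteration(a, np.full(n, 1.0 / n))
        return SiteDistribution.renormalized(M.atlas, pi)
    return SiteDistribution.renormalized(M.atlas, np.abs(w))


@dataclass(frozen=True)
class StateTrajectory:
    """Markov-chain state history ``states[k] = v_k``, with convergence info."""

    states: tuple[SiteDistribution, ...]
    converged: bool
    #: number of steps actually taken (index of the final state)
    final_k: int

    @property
    def final_state(self) -> SiteDistribution:
        return self.states[-1]


def evolve_to_convergence(
    v0: SiteDistribution,
    M: TransitionMatrix,
    tol: float = 1e-6,
    max_k: int = 100,
) -> StateTrajectory:
    """Iterate ``v_{k+1} = v_k @ A`` until successive states are within ``tol``.

    The distance is the Euclidean norm of the state difference.  If
    ``max_k`` is reached first, the trajectory is returned with
    ``converged=False`` (no exception): periodic chains oscillate forever.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    states = [v0]
    for k in range(1, int(max_k) + 1):
        nxt = propagate(states[-1], M, 1)
        states.append(nxt)
        if float(np.linalg.norm(nxt.p - states[-2].p)) < tol:
            return StateTrajectory(tuple(states), True, k)
    return StateTrajectory(tuple(states), False, int(max_k))
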