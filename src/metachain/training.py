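"""Iterative training of a transition matrix to a prescribed stationary state.

The inverse problem — find a row-stochastic matrix whose stationary
distribution equals a given metastatic target distribution — is heavily
underdetermined (N^2 unknowns, N constraints).  Instead of a closed-form
regularized solution, the search is pre-conditioned on a rank-2 initial
matrix built from data (:func:`build_initial_matrix`) and then refined by
randomized local adjustments (:func:`train`):

1. compute the residual ``r = stationary(A) - target``;
2. locate the most over-represented column (argmax of ``r``) and the most
   under-represented column (argmin of ``r``);
3. pick a row uniformly at random;
4. move a small amount ``delta`` of probability mass within that row from
   the over-represented column to the under-represented one, preserving
   the row sum exactly;
5. repeat until the Euclidean residual norm falls below ``epsilon``.

``delta`` is proportional to the current residual norm, so steps shrink as
the iteration closes in on the target.  Because the adjustments are
randomized, repeated runs from the same initialization yield an ensemble
of distinct solutions (see :mod:`metachain.ensemble`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .atlas import SiteAtlas, SiteDistribution
from .markov import TransitionMatrix, require_valid, _power_iteration

__all__ = [
    "TrainConfig",
    "ConvergenceTrace",
    "TrainingError",
    "build_initial_matrix",
    "residual",
    "train",
    "perturb_initial",
    "rank_two_noise",
]


class TrainingError(RuntimeError):
    """The training iteration could not proceed."""


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the randomized training iteration.

    Attributes
    ----------
    epsilon
        Convergence threshold on the Euclidean residual norm.
    delta_scale
        The adjustment step is ``delta_scale * ||residual||`` (further
        capped so entries stay in [0, 1]).
    max_iterations
        Iteration budget; exceeded budgets return the best-so-far matrix
        with ``converged=False`` rather than raising.
    seed
        Seed for the row-selection random stream.
    clip_mode
        ``"reject_row"`` re-draws the row when the entry to decrease is
        already 0; ``"clamp"`` keeps the row and caps the step (possibly
        to a no-op).
    """

    epsilon: float = 1e-3
    delta_scale: float = 0.1
    max_iterations: int = 2_000_000
    seed: int = 0
    clip_mode: str = "reject_row"

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.delta_scale <= 0:
            raise ValueError("delta_scale must be > 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.clip_mode not in ("reject_row", "clamp"):
            raise ValueError(f"unknown clip_mode {self.clip_mode!r}")


@dataclass(frozen=True)
class ConvergenceTrace:
    """Residual-norm history of one training run.

    ``residual_norms[0]`` is the residual of the initial matrix and
    ``residual_norms[j]`` the residual after the j-th accepted adjustment;
    the final entry is <= epsilon exactly when ``converged``.
    """

    residual_norms: np.ndarray = field(repr=False)
    iterations: int
    converged: bool


def build_initial_matrix(
    target: SiteDistribution,
    generic: SiteDistribution,
    primary_site: int,
) -> TransitionMatrix:
    """Rank-2 initial matrix: target on the primary row, generic elsewhere.

    The primary site's outgoing edges are initialized with the target
    distribution (the metastatic distribution conditioned on that primary),
    and every other row with the generic distribution pooled over all
    primaries — an agnostic guess for how non-primary sites communicate.
    With two distinct rows the matrix has numerical rank exactly 2.
    """
    if target.atlas != generic.atlas:
        raise ValueError("target and generic must share an atlas")
    atlas = target.atlas
    a = np.tile(generic.p, (atlas.n, 1))
    a[atlas.index(primary_site)] = target.p
    return TransitionMatrix(atlas, a)


def residual(
    M: TransitionMatrix, target: SiteDistribution, _pi: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """Residual vector ``stationary(M) - target`` and its Euclidean norm."""
    if _pi is None:
        from .markov import stationary_distribution

        _pi = stationary_distribution(M, method="power").p
    r = _pi - target.p
    return r, float(np.linalg.norm(r))


def train(
    A0: TransitionMatrix,
    target: SiteDistribution,
    cfg: TrainConfig = TrainConfig(),
) -> tuple[TransitionMatrix, ConvergenceTrace]:
    """Adjust ``A0`` until its stationary distribution matches ``target``.

    Returns the trained matrix and the per-iteration residual-norm trace.
    Every accepted iteration preserves row sums exactly and keeps all
    entries in [0, 1], so every intermediate matrix is a valid transition
    matrix.  The stationary distribution is recomputed each iteration by
    power iteration warm-started from the previous stationary vector.

    If ``max_iterations`` is exhausted the best matrix seen so far is
    returned with ``converged=False``.
    """
    require_valid(A0)
    if target.atlas != A0.atlas:
        raise ValueError("matrix and target must share an atlas")
    rng = np.random.default_rng(cfg.seed)
    a = A0.a.copy()
    n = a.shape[0]

    pi = _power_iteration(a, np.full(n, 1.0 / n))
    r = pi - target.p
    norm = float(np.linalg.norm(r))
    norms = [norm]
    best_a, best_norm = a.copy(), norm

    iterations = 0
    while norm > cfg.epsilon and iterations < cfg.max_iterations:
        cmax = int(np.argmax(r))  # over-represented site (first max wins)
        cmin = int(np.argmin(r))  # under-represented site
        if cmax == cmin:
            break  # flat residual; nothing to move
        delta = cfg.delta_scale * norm

        if cfg.clip_mode == "reject_row":
            row = -1
            for _ in range(100 * n):
                cand = int(rng.integers(n))
                if a[cand, cmax] > 0.0:
                    row = cand
                    break
            if row < 0:
                # deterministic fallback: lowest-id row that can give mass
                feasible = np.nonzero(a[:, cmax] > 0.0)[0]
                if feasible.size == 0:
                    raise TrainingError(
                        f"no row has mass in column {cmax + 1}; cannot adjust"
                    )
                row = int(feasible[0])
        else:  # clamp
            row = int(rng.integers(n))

        step = min(delta, a[row, cmax], 1.0 - a[row, cmin])
        a[row, cmax] -= step
        a[row, cmin] += step

        pi = _power_iteration(a, pi)
        r = pi - target.p
        norm = float(np.linalg.norm(r))
        norms.append(norm)
        iterations += 1
        if norm < best_norm:
            best_norm = norm
            best_a = a.copy()

    converged = norm <= cfg.epsilon
    if not converged:
        a, norm = best_a, best_norm
        norms[-1] = best_norm
    trace = ConvergenceTrace(np.asarray(norms), iterations, converged)
    return TransitionMatrix(A0.atlas, a), trace


def rank_two_noise(atlas: SiteAtlas, primary_site: int, seed: int) -> np.ndarray:
    """Unscaled rank-2 noise matrix used by :func:`perturb_initial`.

    The primary row receives one vector of iid Uniform[-1, 1] entries and
    all other rows share a second such vector, mirroring the two-row
    structure of the rank-2 initialization.
    """
    rng = np.random.default_rng(seed)
    u_primary = rng.uniform(-1.0, 1.0, atlas.n)
    u_other = rng.uniform(-1.0, 1.0, atlas.n)
    e = np.tile(u_other, (atlas.n, 1))
    e[atlas.index(primary_site)] = u_primary
    return e


def perturb_initial(
    A0: TransitionMatrix,
    rel_size: float = 0.05,
    primary_site: int | None = None,
    seed: int = 0,
) -> TransitionMatrix:
    """Add scaled rank-2 noise to the initial matrix (robustness experiment).

    The noise is scaled so its mean absolute value equals ``rel_size``
    times the mean entry of ``A0`` (i.e. a perturbation of roughly
    ``100 * rel_size`` percent relative to the average row value), then the
    result is clamped to [0, 1] and rows are renormalized to sum to 1.

    Used to show that training is robust: ensembles trained from ``A0``
    and from a 5%-perturbed ``A0`` have statistically indistinguishable
    singular-value spectra.
    """
    if not (0.0 <= rel_size < 1.0):
        raise ValueError("rel_size must be in [0, 1)")
    if rel_size == 0.0:
        return TransitionMatrix(A0.atlas, A0.a)
    if primary_site is None:
        raise ValueError("primary_site is required for a nonzero perturbation")
    e = rank_two_noise(A0.atlas, primary_site, seed)
    scale = rel_size * float(A0.a.mean()) / float(np.abs(e).mean())
    a = np.clip(A0.a + scale * e, 0.0, 1.0)
    a /= a.sum(axis=1, keepdims=True)
    return TransitionMatrix(A0.atlas, a)


def with_seed(cfg: TrainConfig, seed: int) -> TrainConfig:
    """Copy of a config with only the seed replaced."""
    return replace(cfg, seed=int(seed))
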