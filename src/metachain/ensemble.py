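"""Ensembles of trained matrices and their statistical diagnostics.

The randomized training iteration, stopped at a finite threshold, does not
produce a unique matrix: repeating it with different random streams yields
an ensemble of solutions.  Edge values (transition probabilities) across
the ensemble behave as approximately normally distributed random variables
with a characteristic mean and spread, and the singular-value spectrum of
the ensemble is the principal diagnostic of its structure: the number of
non-negligible singular values equals the number of sites that carry
incoming probability mass, and the spectrum decays approximately as a
power law in the index.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .atlas import SiteDistribution
from .markov import TransitionMatrix
from .training import TrainConfig, train

__all__ = [
    "MatrixEnsemble",
    "EdgeSamples",
    "SpectrumSummary",
    "EnsembleError",
    "SpectrumError",
    "train_ensemble",
    "mean_matrix",
    "edge_statistics",
    "singular_values",
    "singular_spectrum",
    "fit_spectrum_slope",
]


class EnsembleError(RuntimeError):
    """Ensemble construction failed (e.g. repeated non-convergence)."""


class SpectrumError(ValueError):
    """Invalid request on a singular-value spectrum."""


@dataclass(frozen=True)
class MatrixEnsemble:
    """Converged matrices trained from one initialization with distinct seeds."""

    members: tuple[TransitionMatrix, ...]
    config: TrainConfig
    seeds: tuple[int, ...]
    #: final residual norm of each member (all <= config.epsilon)
    residual_norms: tuple[float, ...]
    #: number of non-converged runs that were re-drawn with a fresh seed
    n_retried: int = 0

    @property
    def n(self) -> int:
        return len(self.members)

    @property
    def atlas(self):
        return self.members[0].atlas


@dataclass(frozen=True)
class EdgeSamples:
    """Sample statistics of one edge weight across an ensemble."""

    from_site: int
    to_site: int
    mean: float
    std: float
    samples: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class SpectrumSummary:
    """Per-index sample mean/std of ensemble singular values (descending)."""

    mean_sv: np.ndarray = field(repr=False)
    std_sv: np.ndarray = field(repr=False)
    effective_rank: int
    zero_tol: float
    slope: float | None = None


def train_ensemble(
    A0: TransitionMatrix,
    target: SiteDistribution,
    n: int,
    cfg: TrainConfig = TrainConfig(),
    retry_budget: int | None = None,
) -> MatrixEnsemble:
    """Train ``n`` converged matrices from ``A0`` with independent seeds.

    Member seeds are derived deterministically from ``cfg.seed`` via a
    seed sequence, so two calls with the same configuration produce
    identical ensembles.  A member that fails to converge within the
    iteration budget is re-drawn with the next derived seed; more than
    ``retry_budget`` such re-draws raise :class:`EnsembleError`.
    """
    if n < 1:
        raise ValueError("ensemble size must be >= 1")
    if retry_budget is None:
        retry_budget = max(10, n // 2)
    # 2**31 keeps derived seeds in the portable positive-int32 range
    derived = [
        int(s) % 2**31
        for s in np.random.SeedSequence(cfg.seed).generate_state(n + retry_budget)
    ]
    members: list[TransitionMatrix] = []
    seeds: list[int] = []
    norms: list[float] = []
    retried = 0
    pos = 0
    while len(members) < n:
        if pos >= len(derived):
            raise EnsembleError(
                f"exhausted retry budget ({retry_budget}) while training ensemble"
            )
        seed = derived[pos]
        pos += 1
        matrix, trace = train(A0, target, replace(cfg, seed=seed))
        if not trace.converged:
            retried += 1
            continue
        members.append(matrix)
        seeds.append(seed)
        norms.append(float(trace.residual_norms[-1]))
    return MatrixEnsemble(
        tuple(members), cfg, tuple(seeds), tuple(norms), n_retried=retried
    )


def mean_matrix(e: MatrixEnsemble) -> TransitionMatrix:
    """Entrywise ensemble-mean matrix (row-stochastic by linearity)."""
    a = np.mean([m.a for m in e.members], axis=0)
    return TransitionMatrix(e.atlas, a)


def _members(e) -> list[TransitionMatrix]:
    members = list(e.members) if isinstance(e, MatrixEnsemble) else list(e)
    if not members:
        raise ValueError("empty ensemble")
    return members


def _member_arrays(e) -> list[np.ndarray]:
    return [m.a for m in _members(e)]


def edge_statistics(e, from_site: int, to_site: int) -> EdgeSamples:
    """Sample mean/std (ddof=1) of one transition probability across members."""
    members = _members(e)
    arrays = [m.a for m in members]
    atlas = members[0].atlas
    i, j = atlas.index(from_site), atlas.index(to_site)
    samples = np.array([a[i, j] for a in arrays])
    std = float(samples.std(ddof=1)) if samples.size > 1 else 0.0
    return EdgeSamples(from_site, to_site, float(samples.mean()), std, samples)


def singular_values(M: TransitionMatrix) -> np.ndarray:
    """Singular values of one matrix, descending.

    For any row-stochastic matrix the largest singular value is at least 1,
    since the all-ones vector is mapped to itself.
    """
    return np.linalg.svd(M.a, compute_uv=False)


def singular_spectrum(e, zero_tol: float = 1e-6) -> SpectrumSummary:
    """Per-index mean/std of singular values across an ensemble.

    ``effective_rank`` counts mean singular values above ``zero_tol``
    relative to the largest mean singular value (a scale-free cutoff).
    Accepts a :class:`MatrixEnsemble` or any iterable of matrices; a
    single-member "ensemble" gives std 0 everywhere.
    """
    if zero_tol <= 0:
        raise ValueError("zero_tol must be > 0")
    arrays = _member_arrays(e)
    svs = np.array([np.linalg.svd(a, compute_uv=False) for a in arrays])
    mean_sv = svs.mean(axis=0)
    std_sv = svs.std(axis=0, ddof=1) if svs.shape[0] > 1 else np.zeros_like(mean_sv)
    effective_rank = int(np.sum(mean_sv > zero_tol * mean_sv[0]))
    return SpectrumSummary(mean_sv, std_sv, effective_rank, zero_tol)


def fit_spectrum_slope(
    s: SpectrumSummary, index_range: tuple[int, int] | None = None
) -> float:
    """Least-squares slope of ``log(sigma_n)`` vs ``log(n)`` over an index range.

    Indices are 1-based.  The default range is ``(2, effective_rank - 1)``:
    the dominant singular value reflects row-stochasticity rather than the
    decay law, so the fit starts at the second value.  A slope near -1
    means the spectrum decays roughly like ``1/n``.
    """
    if index_range is None:
        index_range = (2, s.effective_rank - 1)
    lo, hi = int(index_range[0]), int(index_range[1])
    if lo < 1 or hi > len(s.mean_sv):
        raise SpectrumError(f"index range {index_range} out of bounds")
    if hi - lo + 1 < 3:
        raise SpectrumError("need at least 3 points to fit a slope")
    n = np.arange(lo, hi + 1, dtype=float)
    sigma = s.mean_sv[lo - 1 : hi]
    if np.any(sigma <= 0):
        raise SpectrumError("singular values in the fit range must be positive")
    slope = float(np.polyfit(np.log(n), np.log(sigma), 1)[0])
    return slope
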