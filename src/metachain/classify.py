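"""Edge ranking, first/second-order site classification, and pathways.

Given a trained matrix (or an ensemble of them), the one-step transition
probabilities out of the primary site rank the most likely first sites of
spread.  Comparing each destination's direct one-step probability against
its best two-step path (through the most probable intermediate site)
splits the metastatic sites into:

* *first-order* sites — the direct edge from the primary dominates;
* *second-order* sites — a two-step route through an intermediate (most
  often the regional lymph nodes or adrenal) is at least as probable,
  once the one-step standard deviation is taken into account.

The classification inequality is: a site is second-order iff

    best_two_step_probability >= one_step_mean - one_step_std

with two-step probabilities formed as products of ensemble-mean edge
values.  Diagonal (self) edges quantify each site's capacity to re-seed
itself, and :func:`pathway_decomposition` enumerates first-passage paths
to a destination with their probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .ensemble import MatrixEnsemble, mean_matrix
from .markov import TransitionMatrix

__all__ = [
    "EdgeStat",
    "TwoStepResult",
    "SiteOrderLabel",
    "SelfEdge",
    "CoverageError",
    "PathBudgetError",
    "FIRST_ORDER",
    "SECOND_ORDER",
    "one_step_probabilities",
    "best_two_step",
    "classify_sites",
    "self_seeding_ranking",
    "pathway_decomposition",
]

FIRST_ORDER = "first_order"
SECOND_ORDER = "second_order"


class CoverageError(ValueError):
    """One- and two-step inputs do not cover the same site set."""


class PathBudgetError(RuntimeError):
    """Path enumeration exceeded its combinatorial budget."""


@dataclass(frozen=True)
class EdgeStat:
    """One directed edge with ensemble mean and spread."""

    from_site: int
    to_site: int
    mean: float
    std: float = 0.0


@dataclass(frozen=True)
class TwoStepResult:
    """Best two-step path to a destination via one intermediate site."""

    destination: int
    best_intermediate: int
    probability: float


@dataclass(frozen=True)
class SiteOrderLabel:
    site: int
    label: str


@dataclass(frozen=True)
class SelfEdge:
    site: int
    mean: float
    std: float = 0.0


def _as_matrix(m) -> TransitionMatrix:
    if isinstance(m, MatrixEnsemble):
        return mean_matrix(m)
    return m


def one_step_probabilities(m_or_stats, source: int) -> list[EdgeStat]:
    """Outgoing edges of ``source``, sorted by descending mean weight.

    Accepts a :class:`TransitionMatrix` (std 0), a
    :class:`MatrixEnsemble` (sample mean/std across members), or a
    pre-computed iterable of :class:`EdgeStat` which is filtered to the
    source and re-sorted.  Ties are broken by ascending site id.
    """
    if isinstance(m_or_stats, MatrixEnsemble):
        arrays = np.array([m.a for m in m_or_stats.members])
        atlas = m_or_stats.atlas
        i = atlas.index(source)
        means = arrays[:, i, :].mean(axis=0)
        stds = (
            arrays[:, i, :].std(axis=0, ddof=1)
            if arrays.shape[0] > 1
            else np.zeros(atlas.n)
        )
        edges = [
            EdgeStat(source, j + 1, float(means[j]), float(stds[j]))
            for j in range(atlas.n)
        ]
    elif isinstance(m_or_stats, TransitionMatrix):
        atlas = m_or_stats.atlas
        row = m_or_stats.a[atlas.index(source)]
        edges = [EdgeStat(source, j + 1, float(row[j])) for j in range(atlas.n)]
    else:
        edges = [e for e in m_or_stats if e.from_site == source]
    return sorted(edges, key=lambda e: (-e.mean, e.to_site))


def best_two_step(m, source: int, destination: int) -> TwoStepResult:
    """Most probable two-step path source -> intermediate -> destination.

    Maximizes the product of the two edge means over every intermediate
    site (self-loops allowed, so the destination or source may serve as
    its own intermediate).  For an ensemble, edge means are the
    ensemble-average matrix entries, i.e. the product of means rather
    than the mean of products.  Ties resolve to the lowest site id.
    """
    M = _as_matrix(m)
    atlas = M.atlas
    s, d = atlas.index(source), atlas.index(destination)
    products = M.a[s, :] * M.a[:, d]
    best = int(np.argmax(products))
    return TwoStepResult(destination, best + 1, float(products[best]))


def classify_sites(
    one_step: Sequence[EdgeStat], two_step: Sequence[TwoStepResult]
) -> list[SiteOrderLabel]:
    """Label each site first- or second-order.

    A site is second-order iff its best two-step probability is greater
    than or equal to its one-step mean minus one standard deviation;
    otherwise first-order.  Input order is preserved in the output.
    """
    two_by_site = {t.destination: t for t in two_step}
    one_sites = [e.to_site for e in one_step]
    if set(one_sites) != set(two_by_site) or len(one_sites) != len(set(one_sites)):
        missing = set(one_sites) ^ set(two_by_site)
        raise CoverageError(
            f"one- and two-step inputs must cover the same sites; mismatch: {sorted(missing)}"
        )
    labels = []
    for e in one_step:
        second = two_by_site[e.to_site].probability >= e.mean - e.std
        labels.append(SiteOrderLabel(e.to_site, SECOND_ORDER if second else FIRST_ORDER))
    return labels


def self_seeding_ranking(m) -> list[SelfEdge]:
    """Diagonal (site -> itself) edge weights, strongest first.

    A positive diagonal entry means a walker can re-seed the site it just
    left in a single step.  For an ensemble, means and stds are taken
    across members; ties are broken by ascending site id.
    """
    if isinstance(m, MatrixEnsemble):
        diags = np.array([np.diag(member.a) for member in m.members])
        means = diags.mean(axis=0)
        stds = diags.std(axis=0, ddof=1) if diags.shape[0] > 1 else np.zeros_like(means)
    else:
        means = np.diag(m.a)
        stds = np.zeros_like(means)
    edges = [
        SelfEdge(i + 1, float(means[i]), float(stds[i])) for i in range(len(means))
    ]
    return sorted(edges, key=lambda e: (-e.mean, e.site))


def pathway_decomposition(
    m,
    source: int,
    destination: int,
    max_length: int = 2,
    prob_floor: float = 1e-8,
    budget: int = 100_000,
) -> list[tuple[tuple[int, ...], float]]:
    """All first-passage paths source -> destination up to ``max_length`` edges.

    A first-passage path visits the destination only as its final site;
    intermediate sites may repeat.  Each path's probability is the product
    of its edge weights; paths below ``prob_floor`` are pruned.  Results
    are sorted by descending probability (ties by path).  Exploring more
    than ``budget`` edges raises :class:`PathBudgetError`.
    """
    if max_length < 1:
        raise ValueError("max_length must be >= 1")
    M = _as_matrix(m)
    atlas = M.atlas
    a = M.a
    d = atlas.index(destination)
    results: list[tuple[tuple[int, ...], float]] = []
    expanded = 0
    stack: list[tuple[int, tuple[int, ...], float]] = [
        (atlas.index(source), (source,), 1.0)
    ]
    while stack:
        node, path, prob = stack.pop()
        for j in np.nonzero(a[node] > 0)[0]:
            j = int(j)
            p2 = prob * a[node, j]
            if p2 <= prob_floor:
                continue
            expanded += 1
            if expanded > budget:
                raise PathBudgetError(
                    f"pathway enumeration exceeded budget of {budget} expansions"
                )
            # len(path) edges would be used by the step node -> j
            if j == d:
                if len(path) <= max_length:
                    results.append((path + (j + 1,), p2))
            elif len(path) < max_length:  # room to reach the destination later
                stack.append((j, path + (j + 1,), p2))
    results.sort(key=lambda t: (-t[1], t[0]))
    return results
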