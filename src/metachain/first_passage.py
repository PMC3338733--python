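"""Mean first-passage times: the model's proxy timescale of progression.

The mean first-passage time (MFPT) from a source site to a destination is
the expected number of steps a random walker on the transition matrix
takes to first arrive at the destination.  Walkers leaving the primary
tumor site reach nearby strongly-connected sites (regional lymph nodes,
adrenal) in a few steps and weakly-connected sites in hundreds, providing
a relative time-ordering of metastatic spread.

Two routes are provided and cross-check each other:

* :func:`mfpt_monte_carlo` follows an ensemble of simulated walkers until
  every target site has been visited, collecting first-visit step counts;
* :func:`mfpt_analytic` makes the destination absorbing and solves the
  fundamental-matrix linear system ``(I - Q) m = 1`` over the transient
  states, giving the exact expectation.

MFPT tables are conventionally normalized by the passage time to a
reference site (regional lymph nodes), so entries read as relative
timescales.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .markov import TransitionMatrix, require_valid

__all__ = [
    "WalkRecord",
    "MFPTTable",
    "ReliabilityWarning",
    "UnreachableSiteError",
    "simulate_walk",
    "mfpt_monte_carlo",
    "mfpt_analytic",
    "normalize_mfpt",
]


class ReliabilityWarning(UserWarning):
    """Too many truncated walks: Monte-Carlo estimates may be biased."""


class UnreachableSiteError(ValueError):
    """Raised where an infinite MFPT cannot be expressed in the result."""


@dataclass(frozen=True)
class WalkRecord:
    """One realized random walk with per-site first-visit step indices."""

    path: tuple[int, ...]
    first_visit: dict[int, int]
    truncated: bool


@dataclass(frozen=True)
class MFPTTable:
    """Per-destination MFPT statistics from one source site.

    ``data`` is indexed by destination site id with columns ``site``
    (name), ``mean``, ``std`` (dispersion of first-visit steps across
    walkers), ``n`` (walkers contributing); after :func:`normalize_mfpt`
    also ``normalized`` and ``normalized_std`` (both divided by the
    reference site's mean).
    """

    source: int
    data: pd.DataFrame = field(repr=False)
    reference_site: int | None = None
    truncated_fraction: float = 0.0


def _check_rows(M: TransitionMatrix) -> np.ndarray:
    a = M.a
    if np.any(a.sum(axis=1) <= 0):
        bad = int(np.argmin(a.sum(axis=1))) + 1
        raise ValueError(f"row {bad} has no outgoing probability mass")
    return a


def simulate_walk(
    M: TransitionMatrix,
    start: int,
    targets: set[int] | None = None,
    seed: int = 0,
    max_steps: int = 1_000_000,
) -> WalkRecord:
    """Simulate one walker until all target sites are visited.

    Each step samples the next site from the current row of the matrix.
    ``targets`` defaults to every site of the atlas.  If ``max_steps`` is
    reached first the record is flagged truncated.  A visit at step 0 (the
    start site itself) counts.
    """
    require_valid(M)
    a = _check_rows(M)
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    atlas = M.atlas
    if targets is None:
        targets = set(atlas.site_ids)
    target_idx = {atlas.index(t) for t in targets}
    rng = np.random.default_rng(seed)
    cum = np.cumsum(a, axis=1)

    cur = atlas.index(start)
    path = [cur + 1]
    first_visit: dict[int, int] = {}
    if cur in target_idx:
        first_visit[cur + 1] = 0
    remaining = target_idx - {cur}
    steps = 0
    while remaining and steps < max_steps:
        cur = int(np.searchsorted(cum[cur], rng.random(), side="right"))
        steps += 1
        path.append(cur + 1)
        if cur in remaining:
            first_visit[cur + 1] = steps
            remaining.discard(cur)
    return WalkRecord(tuple(path), first_visit, truncated=bool(remaining))


def mfpt_monte_carlo(
    M: TransitionMatrix,
    start: int,
    targets: set[int] | None = None,
    n_walkers: int = 10_000,
    seed: int = 0,
    max_steps: int = 1_000_000,
    max_truncated_frac: float = 0.01,
) -> MFPTTable:
    """Monte-Carlo MFPT from ``start`` to each target site.

    Follows ``n_walkers`` independent walkers, each until all targets are
    visited (or ``max_steps``).  Means and standard deviations are over
    walkers; a walker truncated before visiting a given target is excluded
    from that target's statistics, and a truncated fraction above
    ``max_truncated_frac`` raises a :class:`ReliabilityWarning`.

    Arrivals are counted from step 1, so if the start site is itself a
    target its entry is the mean first-return time, not 0.

    The walk is advanced for all walkers simultaneously, so run time
    scales with the longest cover time rather than with ``n_walkers``.
    """
    require_valid(M)
    a = _check_rows(M)
    if n_walkers < 1:
        raise ValueError("n_walkers must be >= 1")
    atlas = M.atlas
    if targets is None:
        targets = set(atlas.site_ids)
    target_ids = sorted(targets)
    t_idx = np.array([atlas.index(t) for t in target_ids])
    col_of = -np.ones(atlas.n, dtype=int)
    col_of[t_idx] = np.arange(len(target_ids))

    rng = np.random.default_rng(seed)
    cum = np.cumsum(a, axis=1)
    start_idx = atlas.index(start)

    first = np.full((n_walkers, len(target_ids)), -1, dtype=np.int64)
    cur = np.full(n_walkers, start_idx, dtype=int)
    active = np.arange(n_walkers)

    for step in range(1, max_steps + 1):
        u = rng.random(active.size)
        rows = cum[cur[active]]
        nxt = (u[:, None] > rows).sum(axis=1)
        cur[active] = nxt
        cols = col_of[nxt]
        hit = cols >= 0
        if hit.any():
            w = active[hit]
            c = cols[hit]
            unseen = first[w, c] < 0
            first[w[unseen], c[unseen]] = step
            done = (first[active] >= 0).all(axis=1)
            active = active[~done]
            if active.size == 0:
                break

    truncated_frac = float(active.size) / n_walkers
    if truncated_frac > max_truncated_frac:
        warnings.warn(
            f"{active.size} of {n_walkers} walks truncated at {max_steps} steps; "
            "MFPT estimates exclude them and may be biased low",
            ReliabilityWarning,
            stacklevel=2,
        )

    rows_out = []
    for k, site in enumerate(target_ids):
        vals = first[:, k]
        vals = vals[vals >= 0].astype(float)
        mean = float(vals.mean()) if vals.size else np.nan
        std = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        rows_out.append((site, atlas.name_of(site), mean, std, int(vals.size)))
    data = pd.DataFrame(
        rows_out, columns=["site_id", "site", "mean", "std", "n"]
    ).set_index("site_id")
    return MFPTTable(start, data, truncated_fraction=truncated_frac)


def _forward_reachable(a: np.ndarray, seeds: list[int], blocked: int) -> set[int]:
    """States reachable from ``seeds`` without stepping beyond ``blocked``."""
    adj = a > 0
    seen: set[int] = set(seeds)
    stack = [s for s in seeds if s != blocked]
    while stack:
        i = stack.pop()
        for j in np.nonzero(adj[i])[0]:
            j = int(j)
            if j not in seen:
                seen.add(j)
                if j != blocked:
                    stack.append(j)
    return seen


def _reaches(a: np.ndarray, target: int) -> set[int]:
    """States from which ``target`` is reachable in >= 1 step."""
    adj = a > 0
    seen = {target}
    stack = [target]
    while stack:
        j = stack.pop()
        for i in np.nonzero(adj[:, j])[0]:
            i = int(i)
            if i not in seen:
                seen.add(i)
                stack.append(i)
    # membership means "can reach target"; the target itself qualifies only
    # if it can return, checked separately by callers that need it
    return seen


def mfpt_analytic(M: TransitionMatrix, start: int, target: int) -> float:
    """Exact MFPT via the fundamental matrix of the absorbing chain.

    The destination is made absorbing and ``(I - Q) m = 1`` is solved over
    the transient states reachable from the source.  Returns ``inf`` when
    the walker has positive probability of never reaching the target
    (target unreachable, or a reachable trap that cannot return).
    For ``start == target`` this is the mean first-return time.
    """
    require_valid(M)
    a = _check_rows(M)
    atlas = M.atlas
    s, t = atlas.index(start), atlas.index(target)

    # states visitable before absorption, walking out of the start
    if s == t:
        seeds = [int(j) for j in np.nonzero(a[t] > 0)[0]]
    else:
        seeds = [s]
    visitable = _forward_reachable(a, seeds, blocked=t)
    can_reach = _reaches(a, t)
    transient = sorted(visitable - {t})
    if s != t and s not in visitable:
        return np.inf
    if any(i not in can_reach for i in transient):
        return np.inf  # positive probability of wandering forever

    if transient:
        q = a[np.ix_(transient, transient)]
        m = np.linalg.solve(np.eye(len(transient)) - q, np.ones(len(transient)))
        m_of = dict(zip(transient, m))
    else:
        m_of = {}

    if s == t:
        return 1.0 + float(
            sum(a[t, j] * m_of[j] for j in seeds if j != t)
        )
    return float(m_of[s])


def normalize_mfpt(table: MFPTTable, reference_site: int) -> MFPTTable:
    """Express all passage times relative to a reference site's mean.

    Adds ``normalized = mean / mean(reference)`` and ``normalized_std =
    std / mean(reference)`` columns; the reference row has normalized
    value exactly 1.
    """
    if reference_site not in table.data.index:
        raise UnreachableSiteError(
            f"reference site {reference_site} not present in the MFPT table"
        )
    ref_mean = float(table.data.loc[reference_site, "mean"])
    if not ref_mean > 0:
        raise UnreachableSiteError(
            f"reference site {reference_site} has non-positive mean {ref_mean}"
        )
    data = table.data.copy()
    data["normalized"] = data["mean"] / ref_mean
    data["normalized_std"] = data["std"] / ref_mean
    return replace(table, data=data, reference_site=reference_site)
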