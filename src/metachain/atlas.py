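"""Site universe and probability vectors over anatomical sites.

The model's state space is a fixed, ordered registry of anatomical sites
(primary tumor locations and potential metastatic sites).  Sites carry
1-based integer ids externally, matching the numbering used in the
published site table; internal array indexing is 0-based.

Every probability-vector quantity in the package — state vectors of the
Markov chain, the metastatic target distribution, the generic (all
primaries) distribution, and stationary distributions — is a
:class:`SiteDistribution` tied to a :class:`SiteAtlas`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SiteAtlas",
    "SiteDistribution",
    "UnknownSiteError",
    "DistributionError",
    "delta_distribution",
    "uniform_distribution",
    "NORMALIZATION_TOL",
]

#: absolute tolerance on |sum(p) - 1| for a valid probability vector
NORMALIZATION_TOL = 1e-9


class UnknownSiteError(KeyError):
    """A site id or name is not part of the atlas."""


class DistributionError(ValueError):
    """A vector is not a valid probability distribution over the atlas."""


@dataclass(frozen=True)
class SiteAtlas:
    """Ordered registry of anatomical sites with contiguous 1-based ids.

    Parameters
    ----------
    names
        Site names in id order; site ``i`` (1-based) is ``names[i-1]``.
        Names must be unique after case-folding.
    """

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) == 0:
            raise ValueError("atlas must contain at least one site")
        folded = [n.casefold() for n in self.names]
        if len(set(folded)) != len(folded):
            dupes = sorted({n for n in folded if folded.count(n) > 1})
            raise ValueError(f"duplicate site names (case-insensitive): {dupes}")

    @property
    def n(self) -> int:
        """Number of sites."""
        return len(self.names)

    @property
    def site_ids(self) -> range:
        """All site ids, 1..n."""
        return range(1, self.n + 1)

    def index(self, site_id: int) -> int:
        """0-based array index for a 1-based site id."""
        if not (1 <= int(site_id) <= self.n):
            raise UnknownSiteError(f"site id {site_id} not in atlas (1..{self.n})")
        return int(site_id) - 1

    def name_of(self, site_id: int) -> str:
        return self.names[self.index(site_id)]

    def id_of(self, name: str) -> int:
        """Site id for a name (case-insensitive)."""
        folded = name.casefold()
        for i, n in enumerate(self.names):
            if n.casefold() == folded:
                return i + 1
        raise UnknownSiteError(f"site name {name!r} not in atlas")

    def __contains__(self, site_id: object) -> bool:
        return isinstance(site_id, (int, np.integer)) and 1 <= int(site_id) <= self.n

    @classmethod
    def from_pairs(cls, pairs: list[tuple[int, str]]) -> "SiteAtlas":
        """Build from (site_id, name) pairs; ids must be contiguous 1..N."""
        ids = [int(i) for i, _ in pairs]
        if sorted(ids) != list(range(1, len(ids) + 1)):
            raise ValueError("site ids must be unique and contiguous 1..N")
        names = [name for _, name in sorted(pairs, key=lambda t: int(t[0]))]
        return cls(tuple(names))

    @classmethod
    def numbered(cls, n: int) -> "SiteAtlas":
        """A placeholder atlas with names ``site_1`` .. ``site_n``."""
        return cls(tuple(f"site_{i}" for i in range(1, n + 1)))


@dataclass(frozen=True)
class SiteDistribution:
    """Probability vector over the sites of an atlas.

    Entries must be non-negative and sum to 1 within ``NORMALIZATION_TOL``.
    Use :meth:`renormalized` for user-supplied vectors that are off by
    rounding (e.g. after a text round-trip).
    """

    atlas: SiteAtlas
    p: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.p, dtype=float).copy()
        arr.setflags(write=False)
        object.__setattr__(self, "p", arr)
        if arr.shape != (self.atlas.n,):
            raise DistributionError(
                f"expected vector of length {self.atlas.n}, got shape {arr.shape}"
            )
        if np.any(arr < 0):
            bad = int(np.argmin(arr)) + 1
            raise DistributionError(f"negative probability at site {bad}: {arr[bad-1]}")
        total = float(arr.sum())
        if abs(total - 1.0) > NORMALIZATION_TOL:
            raise DistributionError(
                f"probabilities sum to {total!r}, not 1 (tolerance {NORMALIZATION_TOL})"
            )

    def __getitem__(self, site_id: int) -> float:
        return float(self.p[self.atlas.index(site_id)])

    def support(self, tol: float = 0.0) -> frozenset[int]:
        """Site ids with probability strictly greater than ``tol``."""
        return frozenset(int(i) + 1 for i in np.nonzero(self.p > tol)[0])

    @classmethod
    def renormalized(cls, atlas: SiteAtlas, p: np.ndarray) -> "SiteDistribution":
        """Clip tiny negative rounding noise and rescale to sum exactly 1."""
        arr = np.clip(np.asarray(p, dtype=float), 0.0, None)
        total = arr.sum()
        if total <= 0:
            raise DistributionError("cannot renormalize a vector with no mass")
        return cls(atlas, arr / total)


def delta_distribution(atlas: SiteAtlas, site_id: int) -> SiteDistribution:
    """Certain knowledge: all probability mass on a single site.

    A delta at the lung site is the canonical initial state for a walker
    representing a primary lung tumor.
    """
    p = np.zeros(atlas.n)
    p[atlas.index(site_id)] = 1.0
    return SiteDistribution(atlas, p)


def uniform_distribution(atlas: SiteAtlas) -> SiteDistribution:
    """Complete ignorance: every site equally likely."""
    return SiteDistribution(atlas, np.full(atlas.n, 1.0 / atlas.n))
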