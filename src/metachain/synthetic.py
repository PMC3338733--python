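"""Synthetic distributions and bundled reference tables.

The real metastatic distributions behind the model come from a large
autopsy series whose per-site probabilities were published only as
histograms, so end-to-end runs use synthetic stand-ins with the same
statistical character: sparse support (a few dozen of the 50 sites) and
heavy tails (a handful of dominant sites, a long tail of rare ones).
Dirichlet sampling on a fixed support with a symmetric concentration
parameter below 1 reproduces that shape with a single knob.

The published summary tables (site numbering, one/two-step lung edges,
self-edge weights, lung MFPTs, dataset counts) ship as checksummed TSV/JSON
fixtures and load through :func:`load_fixtures`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import numpy as np
import pandas as pd

from .atlas import SiteAtlas, SiteDistribution
from .classify import EdgeStat, SelfEdge, TwoStepResult
from .first_passage import MFPTTable

__all__ = [
    "PaperFixtures",
    "FixtureError",
    "StudyConditions",
    "generate_support",
    "generate_target",
    "generate_generic",
    "generate_study",
    "load_fixtures",
]

#: default Dirichlet concentration: < 1 gives the heavy-tailed,
#: few-dominant-sites shape seen in real metastatic distributions
DEFAULT_CONCENTRATION = 0.5


class FixtureError(RuntimeError):
    """Bundled data files are missing or fail checksum verification."""


def generate_support(
    atlas: SiteAtlas,
    size: int,
    seed: int = 0,
    include: Iterable[int] = (),
) -> frozenset[int]:
    """Draw a random support of ``size`` sites, forcing ``include`` in."""
    include = sorted(set(int(i) for i in include))
    for i in include:
        atlas.index(i)
    if not (len(include) <= size <= atlas.n):
        raise ValueError(f"support size {size} out of range for this atlas")
    rng = np.random.default_rng(seed)
    pool = np.array([i for i in atlas.site_ids if i not in include])
    extra = rng.choice(pool, size - len(include), replace=False)
    return frozenset(include) | frozenset(int(i) for i in extra)


def _dirichlet_on_support(
    atlas: SiteAtlas,
    support_sites: Iterable[int],
    concentration: float,
    seed: int,
) -> SiteDistribution:
    support = sorted(set(int(s) for s in support_sites))
    if not support:
        raise ValueError("support must be non-empty")
    if concentration <= 0:
        raise ValueError("concentration must be > 0")
    idx = [atlas.index(s) for s in support]
    rng = np.random.default_rng(seed)
    p = np.zeros(atlas.n)
    p[idx] = rng.dirichlet(np.full(len(idx), float(concentration)))
    return SiteDistribution.renormalized(atlas, p)


def generate_target(
    atlas: SiteAtlas,
    support_sites: Iterable[int],
    concentration: float = DEFAULT_CONCENTRATION,
    seed: int = 0,
) -> SiteDistribution:
    """Synthetic metastatic target distribution on a given support.

    Probabilities on the support are a symmetric Dirichlet draw; all other
    sites are exactly zero, so ``support()`` recovers the support set.
    """
    return _dirichlet_on_support(atlas, support_sites, concentration, seed)


def generate_generic(
    atlas: SiteAtlas,
    support_sites: Iterable[int],
    concentration: float = DEFAULT_CONCENTRATION,
    seed: int = 0,
) -> SiteDistribution:
    """Synthetic all-primaries ("generic") distribution.

    Statistically identical to :func:`generate_target`; kept separate
    because the generic support may be wider than the target's, and the
    two must be drawn with independent seeds so the rank-2 initial matrix
    has two linearly independent rows.
    """
    return _dirichlet_on_support(atlas, support_sites, concentration, seed)


@dataclass(frozen=True)
class StudyConditions:
    """A complete synthetic problem instance: atlas, distributions, primary."""

    atlas: SiteAtlas
    target: SiteDistribution
    generic: SiteDistribution
    primary_site: int


def generate_study(
    seed: int = 0,
    n_sites: int = 50,
    target_support: int = 27,
    generic_support: int = 30,
    primary_site: int = 23,
    concentration: float = DEFAULT_CONCENTRATION,
) -> StudyConditions:
    """Draw a full synthetic study instance emulating the published setup.

    Defaults mirror the original study: 50 sites, a lung-like primary at
    site 23, a 27-site target support contained in a 30-site generic
    support (the sites seen for one primary are a subset of the sites seen
    across all primaries).  All randomness derives from ``seed``.
    """
    if generic_support < target_support:
        raise ValueError("generic support must be at least as wide as the target's")
    sub = [int(s) % 2**31
           for s in np.random.SeedSequence(seed).generate_state(4)]
    atlas = SiteAtlas.numbered(n_sites)
    t_support = generate_support(atlas, target_support, seed=sub[0],
                                 include=(primary_site,))
    g_support = generate_support(atlas, generic_support, seed=sub[1],
                                 include=sorted(t_support))
    target = generate_target(atlas, t_support, concentration, seed=sub[2])
    generic = generate_generic(atlas, g_support, concentration, seed=sub[3])
    return StudyConditions(atlas, target, generic, primary_site)


@dataclass(frozen=True)
class PaperFixtures:
    """Bundled published tables, verified digit-for-digit by checksum.

    The edge, self-edge and MFPT values are ensemble statistics from the
    original 1000-matrix study and are *not* recomputable here (the
    underlying autopsy distributions were never printed); they serve as
    reference inputs for classification and normalization arithmetic.
    """

    atlas: SiteAtlas
    sites: pd.DataFrame = field(repr=False)
    lung_edges: pd.DataFrame = field(repr=False)
    self_edges: pd.DataFrame = field(repr=False)
    mfpt: pd.DataFrame = field(repr=False)
    dataset: dict = field(repr=False)

    @property
    def lung_site(self) -> int:
        return int(self.dataset["lung_site_id"])

    @property
    def reference_site(self) -> int:
        return int(self.dataset["reference_site_id"])

    def lung_target_sites(self) -> frozenset[int]:
        """The sites flagged as part of the lung target distribution."""
        flagged = self.sites[self.sites["in_lung_target"]]
        return frozenset(int(i) for i in flagged.index)

    def one_step_stats(self) -> list[EdgeStat]:
        """Lung outgoing edges as EdgeStat rows, in printed (ranked) order."""
        return [
            EdgeStat(self.lung_site, int(sid), float(r["one_step_mean"]),
                     float(r["one_step_std"]))
            for sid, r in self.lung_edges.iterrows()
        ]

    def two_step_stats(self) -> list[TwoStepResult]:
        return [
            TwoStepResult(int(sid), int(r["two_step_intermediate_id"]),
                          float(r["two_step_prob"]))
            for sid, r in self.lung_edges.iterrows()
        ]

    def self_edge_stats(self) -> list[SelfEdge]:
        return [
            SelfEdge(int(sid), float(r["mean"]), float(r["std"]))
            for sid, r in self.self_edges.iterrows()
        ]

    def mfpt_table(self) -> MFPTTable:
        """The published lung MFPT table as an :class:`MFPTTable`."""
        data = self.mfpt.copy()
        data.index.name = "site_id"
        return MFPTTable(
            source=self.lung_site, data=data, reference_site=self.reference_site
        )


def _data_root():
    return resources.files("metachain.data")


def load_fixtures(verify: bool = True) -> PaperFixtures:
    """Load and checksum-verify the bundled reference tables."""
    root = _data_root()
    manifest = json.loads((root / "manifest.json").read_text())
    if verify:
        for fname, expected in manifest.items():
            digest = hashlib.sha256((root / fname).read_bytes()).hexdigest()
            if digest != expected:
                raise FixtureError(
                    f"checksum mismatch for bundled file {fname}: "
                    f"expected {expected}, got {digest}"
                )

    with (root / "sites.tsv").open() as fh:
        sites = pd.read_csv(fh, sep="\t", index_col="site_id")
    sites["in_lung_target"] = sites["in_lung_target"].map(
        {"true": True, "false": False, True: True, False: False}
    )
    atlas = SiteAtlas(tuple(sites["name"]))

    with (root / "lung_edges.tsv").open() as fh:
        lung_edges = pd.read_csv(fh, sep="\t", index_col="site_id")
    lung_edges = lung_edges.sort_values("rank")
    with (root / "self_edges.tsv").open() as fh:
        self_edges = pd.read_csv(fh, sep="\t", index_col="site_id")
    with (root / "mfpt_lung.tsv").open() as fh:
        mfpt = pd.read_csv(fh, sep="\t", index_col="site_id")
    dataset = json.loads((root / "dataset.json").read_text())

    n_target = int(dataset["n_lung_target_sites"])
    for name, frame in (("lung_edges", lung_edges), ("self_edges", self_edges),
                        ("mfpt", mfpt)):
        if len(frame) != n_target:
            raise FixtureError(f"{name} table has {len(frame)} rows, expected {n_target}")
    return PaperFixtures(atlas, sites, lung_edges, self_edges, mfpt, dataset)
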