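"""Readers and writers for the package's delimited-text artifact files.

All tabular artifacts are tab-separated UTF-8 text with a mandatory
header row and "." as the decimal separator.  Floating-point values are
written with 17 significant digits, so a write/read round-trip reproduces
IEEE doubles bit-exactly.  Site ids in files are always 1-based.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np

from .atlas import (
    NORMALIZATION_TOL,
    SiteAtlas,
    SiteDistribution,
)
from .first_passage import MFPTTable
from .markov import TransitionMatrix
from .training import ConvergenceTrace

__all__ = [
    "ParseError",
    "read_atlas",
    "write_atlas",
    "read_distribution",
    "write_distribution",
    "read_matrix",
    "write_matrix",
    "write_mfpt",
    "write_trace",
    "export_network",
    "write_manifest",
]

_FLOAT_FMT = "%.17g"


class ParseError(ValueError):
    """A file violates the expected layout; the message names the line."""


def _fmt(x: float) -> str:
    return _FLOAT_FMT % float(x)


def read_atlas(path) -> SiteAtlas:
    """Read a 2- or 3-column site table (site_id, name[, flag])."""
    pairs: list[tuple[int, str]] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.strip():
            raise ParseError(f"{path}: empty file or missing header")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected at least 2 columns")
            try:
                sid = int(fields[0])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad site id {fields[0]!r}") from exc
            pairs.append((sid, fields[1]))
    try:
        return SiteAtlas.from_pairs(pairs)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_atlas(atlas: SiteAtlas, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("site_id\tname\n")
        for sid in atlas.site_ids:
            fh.write(f"{sid}\t{atlas.name_of(sid)}\n")


def read_distribution(
    path, atlas: SiteAtlas, renormalize: bool = False
) -> SiteDistribution:
    """Read a (site_id, probability) table covering every atlas site once.

    With ``renormalize`` the vector is rescaled to sum exactly 1, which
    forgives rounding from hand-edited files; otherwise a sum off by more
    than the normalization tolerance is an error.
    """
    p = np.full(atlas.n, np.nan)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.strip():
            raise ParseError(f"{path}: empty file or missing header")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            try:
                sid = int(fields[0])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad site id {fields[0]!r}") from exc
            if not (1 <= sid <= atlas.n):
                raise ParseError(f"{path}:{lineno}: site id {sid} not in atlas")
            if not np.isnan(p[sid - 1]):
                raise ParseError(f"{path}:{lineno}: duplicate site id {sid}")
            try:
                p[sid - 1] = float(fields[1])
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric probability {fields[1]!r}"
                ) from exc
    missing = np.nonzero(np.isnan(p))[0]
    if missing.size:
        raise ParseError(f"{path}: missing site ids {[int(i)+1 for i in missing[:5]]}")
    if renormalize:
        return SiteDistribution.renormalized(atlas, p)
    total = float(p.sum())
    if abs(total - 1.0) > NORMALIZATION_TOL:
        raise ParseError(
            f"{path}: probabilities sum to {total!r}, not 1 "
            "(pass renormalize=True / --renormalize to rescale)"
        )
    return SiteDistribution(atlas, p)


def write_distribution(d: SiteDistribution, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("site_id\tprobability\n")
        for sid in d.atlas.site_ids:
            fh.write(f"{sid}\t{_fmt(d[sid])}\n")


def read_matrix(path, atlas: SiteAtlas | None = None) -> TransitionMatrix:
    """Read a square matrix whose first row and column are site ids.

    Without an explicit atlas a placeholder one (``site_1`` ..) of the
    file's dimension is used.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ParseError(f"{path}: missing matrix header")
        col_ids = [int(c) for c in header[1:]]
        rows = []
        row_ids = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(col_ids) + 1:
                raise ParseError(
                    f"{path}:{lineno}: expected {len(col_ids) + 1} columns, "
                    f"got {len(fields)}"
                )
            row_ids.append(int(fields[0]))
            try:
                rows.append([float(x) for x in fields[1:]])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric entry") from exc
    n = len(col_ids)
    if col_ids != list(range(1, n + 1)) or row_ids != list(range(1, n + 1)):
        raise ParseError(f"{path}: site ids must be contiguous 1..{n} in file order")
    if atlas is None:
        atlas = SiteAtlas.numbered(n)
    elif atlas.n != n:
        raise ParseError(f"{path}: matrix is {n}x{n} but atlas has {atlas.n} sites")
    return TransitionMatrix(atlas, np.asarray(rows))


def write_matrix(M: TransitionMatrix, path) -> None:
    n = M.atlas.n
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("site_id\t" + "\t".join(str(j) for j in range(1, n + 1)) + "\n")
        for i in range(n):
            fh.write(
                str(i + 1) + "\t" + "\t".join(_fmt(x) for x in M.a[i]) + "\n"
            )


def write_mfpt(table: MFPTTable, path) -> None:
    """Write an MFPT table as TSV (site, mean, std[, normalized...])."""
    table.data.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def write_trace(trace: ConvergenceTrace, path) -> None:
    """Per-iteration residual-norm history as CSV (iteration, residual_norm)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("iteration,residual_norm\n")
        for i, r in enumerate(trace.residual_norms):
            fh.write(f"{i},{_fmt(r)}\n")


def export_network(
    M: TransitionMatrix, threshold: float, path, format: str = "graphml"
) -> None:
    """Export the weighted directed graph of all edges above a threshold.

    One node per site (attributes: site id, name), one directed edge per
    matrix entry strictly greater than ``threshold``, with the transition
    probability as the ``weight`` attribute.  Self-loops are included.
    GraphML is the structured format; DOT is for quick rendering.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if format not in ("graphml", "dot"):
        raise ValueError(f"unsupported format {format!r} (use 'graphml' or 'dot')")
    atlas = M.atlas
    g = nx.DiGraph()
    for sid in atlas.site_ids:
        g.add_node(sid, name=atlas.name_of(sid))
    for i, j in np.argwhere(M.a > threshold):
        g.add_edge(int(i) + 1, int(j) + 1, weight=float(M.a[i, j]))
    if format == "graphml":
        nx.write_graphml(g, path)
    else:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("digraph metastasis {\n")
            for sid, data in g.nodes(data=True):
                fh.write(f'  n{sid} [label="{data["name"]}"];\n')
            for u, v, data in g.edges(data=True):
                fh.write(f'  n{u} -> n{v} [weight="{_fmt(data["weight"])}"];\n')
            fh.write("}\n")


def write_manifest(path, payload: dict) -> None:
    """Record inputs, seeds and configuration of a run as JSON."""
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
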