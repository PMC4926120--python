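"""Automatic barcode-gap discovery and distance-based species partitioning.

A barcode library with a "barcode gap" shows two well-separated modes in its
pairwise K2P distance distribution: intraspecific distances (here up to about
2%) and interspecific distances (16% and above).  Partitioning proceeds in
the spirit of automatic barcode gap discovery: given a prior ``P`` (the
maximum presumed intraspecific divergence, as a proportion) the first
sufficiently wide interval between consecutive sorted distances above ``P``
is declared the gap, sequences are linked single-linkage at the gap's lower
edge, and the procedure recurses inside each resulting group until no further
gap is found.

The gap rule: an interval ``(d_i, d_{i+1})`` whose upper edge lies above the
prior (``d_{i+1} >= P``; distances at or below ``P`` are presumed
intraspecific) is a gap when

    d_{i+1} - d_i  >  X * max(mean spacing of distances <= d_i, min_slope)

and its reported lower edge is clamped up to ``P``.

``X`` (relative gap width, default 1.5) follows the widely used default;
``min_slope`` (default 0.01 substitutions/site) floors the local-spacing
estimate so that near-duplicate distances at the bottom of the distribution
cannot make an arbitrarily small interval count as a gap.  In the divergence
regime this toolkit targets the gap is an order of magnitude wider than
either term, so the partition is insensitive to the exact rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .distances import DistanceMatrix
from .errors import DistanceError


@dataclass
class Gap:
    low: float     # largest distance below the gap
    high: float    # smallest distance above the gap

    @property
    def width(self) -> float:
        return self.high - self.low


@dataclass
class GapScan:
    """Sorted pairwise distances and the gap found above the prior, if any."""

    distances: np.ndarray
    prior: float
    X: float
    min_slope: float
    gap: Optional[Gap] = None


@dataclass
class Partition:
    """Assignment of sequence ids to candidate-species groups."""

    group_of: dict[str, int]
    prior: float

    @property
    def n_groups(self) -> int:
        return len(set(self.group_of.values()))

    def groups(self) -> list[list[str]]:
        out: dict[int, list[str]] = {}
        for label, g in self.group_of.items():
            out.setdefault(g, []).append(label)
        return [out[g] for g in sorted(out)]

    def to_tsv(self) -> str:
        lines = ["id\tgroup"]
        for label, g in self.group_of.items():
            lines.append(f"{label}\t{g}")
        return "\n".join(lines) + "\n"


def distance_profile(
    m: DistanceMatrix, bin_width: float = 0.005
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sorted off-diagonal distances plus a histogram.

    Returns ``(values, bin_edges, counts)``; ``bin_width`` is in
    substitutions/site (default 0.5%).
    """
    values = np.sort(m.condensed())
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise DistanceError("no pairwise distances to profile")
    top = max(float(values.max()), bin_width)
    edges = np.arange(0.0, top + bin_width, bin_width)
    counts, edges = np.histogram(values, bins=edges)
    return values, edges, counts


def find_gap(
    distances: Sequence[float],
    prior: float,
    X: float = 1.5,
    min_slope: float = 0.01,
) -> GapScan:
    """Locate the first barcode gap above the prior ``P`` in sorted distances."""
    ds = np.sort(np.asarray(list(distances), dtype=float))
    ds = ds[~np.isnan(ds)]
    if ds.size == 0:
        raise DistanceError("empty distance set")
    scan = GapScan(distances=ds, prior=prior, X=X, min_slope=min_slope)
    if prior >= float(ds.max()):
        return scan
    for i in range(ds.size - 1):
        # distances at or below the prior are presumed intraspecific, so a
        # candidate interval only needs its upper edge above the prior; the
        # reported lower edge is clamped up to the prior
        if ds[i + 1] < prior:
            continue
        width = ds[i + 1] - ds[i]
        if width <= 0:
            continue
        below = np.unique(ds[ds <= ds[i]])
        if below.size > 1:
            mean_spacing = (below[-1] - below[0]) / (below.size - 1)
        else:
            # no local spacing estimate yet: fall back to the global one
            distinct = np.unique(ds)
            mean_spacing = (
                (distinct[-1] - distinct[0]) / (distinct.size - 1)
                if distinct.size > 1 else 0.0
            )
        if width > X * max(mean_spacing, min_slope):
            scan.gap = Gap(low=float(max(ds[i], prior)), high=float(ds[i + 1]))
            break
    return scan


def _components(labels: list[str], values: np.ndarray, cutoff: float) -> list[list[str]]:
    """Connected components linking pairs with distance <= cutoff (union-find)."""
    n = len(labels)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if not np.isnan(values[i, j]) and values[i, j] <= cutoff:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    comps: dict[int, list[str]] = {}
    for i, lab in enumerate(labels):
        comps.setdefault(find(i), []).append(lab)
    return list(comps.values())


def abgd_partition(
    m: DistanceMatrix,
    prior: float,
    X: float = 1.5,
    min_slope: float = 0.01,
    max_depth: int = 10,
) -> Partition:
    """Recursive barcode-gap partition of a distance matrix.

    If a gap is found, sequences whose distance is at most the gap's lower
    edge are linked and the resulting connected components form groups; the
    scan then recurses within each group on the restricted matrix.  Without an
    initial gap the whole library is one group.  Recursion depth is capped
    (default 10) to guarantee termination.
    """
    group_of: dict[str, int] = {}
    next_group = [0]

    def _recurse(sub: DistanceMatrix, depth: int) -> None:
        dists = sub.condensed()
        dists = dists[~np.isnan(dists)]
        if len(sub.labels) < 2 or dists.size == 0 or depth >= max_depth:
            _assign(sub.labels)
            return
        scan = find_gap(dists, prior, X=X, min_slope=min_slope)
        if scan.gap is None:
            _assign(sub.labels)
            return
        comps = _components(sub.labels, sub.values, scan.gap.low)
        if len(comps) == 1:
            _assign(sub.labels)
            return
        for comp in comps:
            _recurse(sub.submatrix(comp), depth + 1)

    def _assign(labels: list[str]) -> None:
        g = next_group[0]
        next_group[0] += 1
        for lab in labels:
            group_of[lab] = g

    _recurse(m, 0)
    return Partition(group_of=group_of, prior=prior)


def partition_scan(
    m: DistanceMatrix,
    priors: Optional[Sequence[float]] = None,
    X: float = 1.5,
    min_slope: float = 0.01,
) -> list[tuple[float, int]]:
    """Number of groups across a range of priors (default 0.001..0.1, log-spaced)."""
    if priors is None:
        priors = np.logspace(-3, -1, 20)
    return [
        (float(p), abgd_partition(m, float(p), X=X, min_slope=min_slope).n_groups)
        for p in priors
    ]
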