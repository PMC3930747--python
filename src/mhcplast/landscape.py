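"""Gibbs free-energy landscapes over the top two principal components.

The joint distribution of (PC1, PC2) is histogrammed, treated as a Boltzmann
ensemble and transformed to a free energy per bin

    G_b = -ln(P_b / P_max)   [kT],

so the most populated bin sits at G = 0 and every occupied bin is
non-negative.  Empty bins are masked (NaN) rather than assigned a
pseudo-count: the molecule never visited them, and inventing an energy there
would fabricate barriers.  Minima are occupied bins below all eight
neighbours; the barrier between two minima is the lowest level at which they
become connected on the occupied-bin graph (a watershed / persistence
computation), minus the higher of the two minimum energies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .essential import ProjectionSeries

__all__ = [
    "EnergyLandscape",
    "Minimum",
    "estimate_density",
    "to_free_energy",
    "find_minima",
    "barrier_height",
    "marginal_density",
]

DEFAULT_BINS = 64
MARGIN_FRACTION = 0.05
KB_KJ_PER_MOL_K = 0.0083144626   # Boltzmann constant in kJ/(mol K)


@dataclass
class HistogramGrid:
    """2-D histogram of the joint (PC1, PC2) distribution."""

    counts: np.ndarray              # (B1, B2)
    centers1: np.ndarray
    centers2: np.ndarray

    @property
    def probabilities(self) -> np.ndarray:
        return self.counts / self.counts.sum()


@dataclass
class Minimum:
    bin_index: tuple[int, int]
    g: float                        # kT
    persistence: float              # kT; inf for the global minimum


@dataclass
class EnergyLandscape:
    """Free energy per (PC1, PC2) bin in kT units; empty bins are NaN."""

    g: np.ndarray                   # (B1, B2), NaN on empty bins
    counts: np.ndarray
    centers1: np.ndarray
    centers2: np.ndarray
    temperature: float = 300.0      # K, reference thermostat
    minima: list[Minimum] = field(default_factory=list)

    @property
    def occupied(self) -> np.ndarray:
        return np.isfinite(self.g)

    def g_kj_per_mol(self) -> np.ndarray:
        return self.g * KB_KJ_PER_MOL_K * self.temperature


def _axis_edges(values: np.ndarray, bins: int, margin: float) -> np.ndarray:
    lo, hi = float(values.min()), float(values.max())
    span = hi - lo
    if span == 0:
        span = max(abs(lo), 1.0)
    pad = margin * span
    if pad == 0 and hi == lo:
        pad = 0.5 * span
    return np.linspace(lo - pad, hi + pad, bins + 1)


def _as_array(p: ProjectionSeries | np.ndarray) -> np.ndarray:
    if isinstance(p, ProjectionSeries):
        if p.values.shape[1] != 1:
            raise ValueError("pass one component at a time")
        return p.values[:, 0]
    return np.asarray(p, dtype=float)


def estimate_density(
    p1: ProjectionSeries | np.ndarray,
    p2: ProjectionSeries | np.ndarray,
    bins: int | tuple[int, int] = DEFAULT_BINS,
    margin: float = MARGIN_FRACTION,
) -> HistogramGrid:
    """Joint histogram of two equally long projection series.

    Bins span the data range plus a ``margin`` fraction per axis (5% by
    default, so the explored region does not touch the grid edge); bin
    probabilities are counts / T and sum to one exactly.
    """
    a, b = _as_array(p1), _as_array(p2)
    if a.shape != b.shape:
        raise ValueError("projection series must have equal length")
    if a.size == 0:
        raise ValueError("cannot estimate a density from zero frames")
    b1, b2 = (bins, bins) if np.isscalar(bins) else bins
    edges1 = _axis_edges(a, b1, margin)
    edges2 = _axis_edges(b, b2, margin)
    counts, _, _ = np.histogram2d(a, b, bins=[edges1, edges2])
    return HistogramGrid(
        counts=counts,
        centers1=0.5 * (edges1[:-1] + edges1[1:]),
        centers2=0.5 * (edges2[:-1] + edges2[1:]),
    )


def to_free_energy(grid: HistogramGrid, temperature: float = 300.0) -> EnergyLandscape:
    """Boltzmann inversion of the histogram: G_b = -ln(P_b / P_max) in kT.

    Invariant under rescaling all counts by a constant; the occupied minimum
    is exactly 0 and empty bins are masked (NaN), never assigned an energy.
    """
    counts = np.asarray(grid.counts, dtype=float)
    if counts.sum() == 0:
        raise ValueError("empty histogram")
    g = np.full(counts.shape, np.nan)
    occupied = counts > 0
    g[occupied] = -np.log(counts[occupied] / counts.max())
    return EnergyLandscape(
        g=g,
        counts=counts,
        centers1=grid.centers1,
        centers2=grid.centers2,
        temperature=temperature,
    )


# ---------------------------------------------------------------------------
# minima and barriers
# ---------------------------------------------------------------------------

_NEIGHBOURS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _local_minima(g: np.ndarray) -> list[tuple[int, int]]:
    """Occupied bins strictly below all occupied 8-neighbours (ties keep the
    lexicographically first bin so plateaus yield a single representative)."""
    minima = []
    b1, b2 = g.shape
    for i in range(b1):
        for j in range(b2):
            if not np.isfinite(g[i, j]):
                continue
            is_min = True
            for di, dj in _NEIGHBOURS:
                ni, nj = i + di, j + dj
                if 0 <= ni < b1 and 0 <= nj < b2 and np.isfinite(g[ni, nj]):
                    if g[ni, nj] < g[i, j] or (g[ni, nj] == g[i, j] and (ni, nj) < (i, j)):
                        is_min = False
                        break
            if is_min:
                minima.append((i, j))
    return minima


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> None:
        self.parent[self.find(a)] = self.find(b)


def find_minima(
    land: EnergyLandscape,
    min_separation: int = 1,
    depth_threshold: float = 1.0,
) -> list[Minimum]:
    """Local minima of the landscape with merging and a depth filter.

    Candidate minima are occupied bins below all occupied 8-neighbours
    (plateau ties keep one representative).  Candidates closer than
    ``min_separation`` bins (Chebyshev distance) are merged, keeping the
    deeper one.  A surviving minimum's persistence is the barrier to reach
    any deeper minimum; minima with persistence below ``depth_threshold``
    kT are discarded (the global minimum has infinite persistence).  The
    result is stored on the landscape and returned sorted by energy.
    """
    if not np.isfinite(land.g).any():
        raise ValueError("fully masked landscape has no minima")
    candidates = sorted(_local_minima(land.g), key=lambda b: land.g[b])
    merged: list[tuple[int, int]] = []
    for cand in candidates:
        if not any(
            max(abs(cand[0] - k[0]), abs(cand[1] - k[1])) <= min_separation
            for k in merged
        ):
            merged.append(cand)
    kept: list[Minimum] = []
    for i, b in enumerate(merged):
        if i == 0:
            persistence = float("inf")
        else:
            persistence = min(barrier_height(land, b, d) for d in merged[:i])
        if not np.isfinite(persistence) and i > 0:
            # disconnected from every deeper minimum (e.g. an isolated
            # sampling speck): its depth is that of its own occupied island
            persistence = _component_depth(land.g, b)
        if persistence >= depth_threshold:
            kept.append(Minimum(bin_index=b, g=float(land.g[b]), persistence=persistence))
    land.minima = kept
    return kept


def _component_depth(g: np.ndarray, start: tuple[int, int]) -> float:
    """Depth of the occupied connected region containing ``start``:
    max G in the region minus G at ``start``."""
    b1, b2 = g.shape
    seen = {start}
    stack = [start]
    gmax = g[start]
    while stack:
        i, j = stack.pop()
        gmax = max(gmax, g[i, j])
        for di, dj in _NEIGHBOURS:
            nb = (i + di, j + dj)
            if (
                0 <= nb[0] < b1 and 0 <= nb[1] < b2
                and nb not in seen and np.isfinite(g[nb])
            ):
                seen.add(nb)
                stack.append(nb)
    return float(gmax - g[start])


def barrier_height(
    land: EnergyLandscape, a: tuple[int, int], b: tuple[int, int]
) -> float:
    """Barrier between two occupied bins: (min over occupied paths of the
    maximum G on the path) minus max(G_a, G_b).

    Symmetric and non-negative; paths may not cross masked bins.  Returns
    inf if the bins lie in disconnected occupied regions.
    """
    g = land.g
    if not (np.isfinite(g[a]) and np.isfinite(g[b])):
        raise ValueError("both bins must be occupied")
    occ = np.argwhere(np.isfinite(g))
    order = np.argsort(g[tuple(occ.T)], kind="stable")
    occ = [tuple(x) for x in occ[order]]
    index = {x: k for k, x in enumerate(occ)}
    uf = _UnionFind(len(occ))
    activated: set[tuple[int, int]] = set()
    for x in occ:
        activated.add(x)
        for di, dj in _NEIGHBOURS:
            nb = (x[0] + di, x[1] + dj)
            if nb in activated:
                uf.union(index[x], index[nb])
        if a in activated and b in activated and uf.find(index[a]) == uf.find(index[b]):
            return float(g[x] - max(g[a], g[b]))
    return float("inf")


def marginal_density(
    p: ProjectionSeries | np.ndarray, bins: int = DEFAULT_BINS
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized 1-D histogram of one projection (centers, probabilities).

    Probabilities sum to one; these are the per-axis densities drawn
    alongside the joint landscape.
    """
    a = _as_array(p)
    if a.size == 0:
        raise ValueError("cannot estimate a density from zero frames")
    edges = _axis_edges(a, bins, MARGIN_FRACTION)
    counts, _ = np.histogram(a, bins=edges)
    return 0.5 * (edges[:-1] + edges[1:]), counts / counts.sum()
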