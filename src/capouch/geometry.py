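"""Synthetic wing-pouch epithelium: Voronoi cells, adjacency, V_PLC fields.

Cells are generated by sampling points uniformly in an elliptical
pouch-like domain, building a Voronoi tessellation clipped to the domain,
and applying a few rounds of Lloyd's relaxation, which drives the packing
towards the near-hexagonal topology of a columnar epithelium.  Coordinates
are normalised so the mean cell diameter is 1; shared-boundary lengths
l_ij are therefore dimensionless and the gap-junction permeabilities Fp
and Fc are used as printed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import shapely
from scipy.spatial import Voronoi
from shapely.geometry import Point, Polygon

__all__ = [
    "TissueGeometry",
    "VplcField",
    "generate_tissue",
    "tissue_from_polygons",
    "load_tissue",
    "save_tissue",
    "assign_vplc",
]

_EDGE_TOL = 1e-9


@dataclass
class TissueGeometry:
    """Cells (centroids, polygons, areas) and the gap-junction contact graph.

    ``edges`` holds each unordered neighbour pair once as ``(i, j)`` with
    ``i < j``; ``edge_lengths`` holds the shared boundary length l_ij.
    ``boundary`` flags cells whose perimeter is not fully accounted for by
    shared edges, i.e. cells touching the tissue margin.
    """

    centroids: np.ndarray          # (N, 2)
    polygons: list                 # list of (k, 2) vertex arrays
    areas: np.ndarray              # (N,)
    edges: np.ndarray              # (E, 2) int, i < j
    edge_lengths: np.ndarray       # (E,)

    def __post_init__(self):
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        self.edge_lengths = np.asarray(self.edge_lengths, dtype=float)
        self.validate()

    @property
    def n_cells(self) -> int:
        return len(self.centroids)

    def validate(self) -> None:
        n = self.n_cells
        if n == 0:
            raise ValueError("tissue must contain at least one cell")
        if len(self.polygons) != n or len(self.areas) != n:
            raise ValueError("centroids, polygons and areas must have equal length")
        if len(self.edges) != len(self.edge_lengths):
            raise ValueError("edges and edge_lengths must have equal length")
        if len(self.edges):
            if self.edges.min() < 0 or self.edges.max() >= n:
                raise ValueError("edge indices out of range")
            if np.any(self.edges[:, 0] >= self.edges[:, 1]):
                raise ValueError("edges must be stored once per pair with i < j")
            keys = set(map(tuple, self.edges))
            if len(keys) != len(self.edges):
                raise ValueError("duplicate edge records")
            if np.any(self.edge_lengths <= 0):
                raise ValueError("all shared boundary lengths must be > 0")
        if np.any(self.areas <= 0):
            raise ValueError("all cell areas must be > 0")

    # -- derived quantities -------------------------------------------

    def neighbor_counts(self) -> np.ndarray:
        counts = np.zeros(self.n_cells, dtype=int)
        for i, j in self.edges:
            counts[i] += 1
            counts[j] += 1
        return counts

    def perimeters(self) -> np.ndarray:
        out = np.empty(self.n_cells)
        for i, poly in enumerate(self.polygons):
            closed = np.vstack([poly, poly[:1]])
            out[i] = np.sum(np.hypot(*np.diff(closed, axis=0).T))
        return out

    @property
    def boundary(self) -> np.ndarray:
        """True for cells whose perimeter exceeds the sum of their shared
        edges, i.e. cells exposed to the tissue margin."""
        shared = np.zeros(self.n_cells)
        for (i, j), l in zip(self.edges, self.edge_lengths):
            shared[i] += l
            shared[j] += l
        per = self.perimeters()
        return (per - shared) > 1e-6 * per

    def interior_mean_neighbors(self) -> float:
        interior = ~self.boundary
        if not interior.any():
            return float("nan")
        return float(self.neighbor_counts()[interior].mean())

    def total_area(self) -> float:
        return float(self.areas.sum())

    def mean_cell_diameter(self) -> float:
        return float(np.mean(np.sqrt(4.0 * self.areas / np.pi)))

    def relabel(self, perm: np.ndarray) -> "TissueGeometry":
        """Apply a cell permutation: new index ``perm[i]`` for old ``i``."""
        perm = np.asarray(perm, dtype=int)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(len(perm))
        edges = np.sort(perm[self.edges], axis=1)
        order = np.lexsort((edges[:, 1], edges[:, 0]))
        return TissueGeometry(
            centroids=self.centroids[inv],
            polygons=[self.polygons[k] for k in inv],
            areas=self.areas[inv],
            edges=edges[order],
            edge_lengths=self.edge_lengths[order],
        )


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _ellipse(n_cells: int, aspect_ratio: float) -> Polygon:
    # unit mean cell area before normalisation: pi*a*b = n_cells
    b = np.sqrt(n_cells / (np.pi * aspect_ratio))
    a = aspect_ratio * b
    circle = Point(0.0, 0.0).buffer(1.0, quad_segs=96)
    return shapely.affinity.scale(circle, a, b)


def _sample_in_polygon(domain: Polygon, n: int, rng: np.random.Generator) -> np.ndarray:
    minx, miny, maxx, maxy = domain.bounds
    pts = []
    while len(pts) < n:
        cand = rng.uniform((minx, miny), (maxx, maxy), size=(4 * n, 2))
        inside = shapely.contains_xy(domain, cand[:, 0], cand[:, 1])
        pts.extend(cand[inside])
    return np.array(pts[:n])


def _clipped_voronoi_cells(points: np.ndarray, domain: Polygon):
    """Voronoi cells of ``points`` clipped to ``domain``.

    A ring of far ghost generators guarantees every real region is finite
    before clipping.  Returns (list of shapely polygons, ridge pair list).
    """
    n = len(points)
    minx, miny, maxx, maxy = domain.bounds
    radius = 3.0 * max(maxx - minx, maxy - miny)
    cx, cy = (minx + maxx) / 2, (miny + maxy) / 2
    angles = np.linspace(0, 2 * np.pi, 64, endpoint=False)
    ghosts = np.column_stack([cx + radius * np.cos(angles), cy + radius * np.sin(angles)])
    vor = Voronoi(np.vstack([points, ghosts]))
    cells = []
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) == 0:
            raise RuntimeError(f"unbounded Voronoi region for cell {i}")
        poly = Polygon(vor.vertices[region]).intersection(domain)
        if poly.is_empty or poly.geom_type != "Polygon":
            raise RuntimeError(f"degenerate clipped cell {i}")
        cells.append(poly)
    ridges = [
        (int(min(a, b)), int(max(a, b)))
        for a, b in vor.ridge_points
        if a < n and b < n
    ]
    return cells, ridges


def tissue_from_polygons(cells: list, candidate_pairs=None) -> TissueGeometry:
    """Build a :class:`TissueGeometry` from shapely cell polygons.

    Shared boundary lengths are measured as the length of the geometric
    intersection of cell boundaries.  ``candidate_pairs`` restricts the
    pairs examined (e.g. Voronoi ridges); all pairs are tested otherwise.
    """
    n = len(cells)
    if n == 0:
        raise ValueError("empty cell list")
    # snap to a fine grid so boundaries of abutting cells coincide exactly
    cells = [shapely.set_precision(p, 1e-9) for p in cells]
    if candidate_pairs is None:
        tree = shapely.STRtree(cells)
        candidate_pairs = set()
        for i, poly in enumerate(cells):
            for j in tree.query(poly.buffer(_EDGE_TOL * 10)):
                j = int(j)
                if j > i:
                    candidate_pairs.add((i, j))
    edges = []
    lengths = []
    for i, j in sorted(set(candidate_pairs)):
        shared = cells[i].boundary.intersection(cells[j].boundary)
        if shared.is_empty:
            continue
        l = shared.length
        if l > _EDGE_TOL:
            edges.append((i, j))
            lengths.append(l)
    edges = np.array(edges, dtype=int).reshape(-1, 2)
    order = np.lexsort((edges[:, 1], edges[:, 0])) if len(edges) else []
    return TissueGeometry(
        centroids=np.array([[p.centroid.x, p.centroid.y] for p in cells]),
        polygons=[np.asarray(p.exterior.coords)[:-1] for p in cells],
        areas=np.array([p.area for p in cells]),
        edges=edges[order] if len(edges) else edges,
        edge_lengths=np.asarray(lengths)[order] if len(edges) else np.array([]),
    )


def _rescale(tissue: TissueGeometry) -> TissueGeometry:
    """Normalise lengths so the mean equivalent cell diameter is 1."""
    d = tissue.mean_cell_diameter()
    return TissueGeometry(
        centroids=tissue.centroids / d,
        polygons=[p / d for p in tissue.polygons],
        areas=tissue.areas / d**2,
        edges=tissue.edges,
        edge_lengths=tissue.edge_lengths / d,
    )


def generate_tissue(
    n_cells: int,
    lloyd_iterations: int = 4,
    seed=0,
    aspect_ratio: float = 1.3,
) -> TissueGeometry:
    """Generate a pouch-like epithelial sheet of ``n_cells`` Voronoi cells.

    Points are sampled uniformly in an ellipse of aspect ratio
    ``aspect_ratio``, tessellated, and relaxed by moving each generator to
    its clipped cell centroid for ``lloyd_iterations`` rounds.
    Deterministic given ``seed``.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if lloyd_iterations < 0:
        raise ValueError("lloyd_iterations must be >= 0")
    rng = _as_rng(seed)
    domain = _ellipse(n_cells, aspect_ratio)
    points = _sample_in_polygon(domain, n_cells, rng)
    if n_cells == 1:
        cells = [domain]
        ridges = []
    else:
        for _ in range(lloyd_iterations):
            cells, _ = _clipped_voronoi_cells(points, domain)
            points = np.array([[c.centroid.x, c.centroid.y] for c in cells])
        cells, ridges = _clipped_voronoi_cells(points, domain)
    tissue = tissue_from_polygons(cells, candidate_pairs=ridges or None)
    if n_cells >= 2:
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(n_cells))
        g.add_edges_from(map(tuple, tissue.edges))
        if not nx.is_connected(g):
            raise RuntimeError("generated adjacency graph is not connected")
    return _rescale(tissue)


def save_tissue(tissue: TissueGeometry, path) -> None:
    """Write geometry as JSON: cells (id, centroid, polygon, area) + edges."""
    payload = {
        "cells": [
            {
                "id": i,
                "centroid": tissue.centroids[i].tolist(),
                "polygon": np.asarray(tissue.polygons[i]).tolist(),
                "area": float(tissue.areas[i]),
            }
            for i in range(tissue.n_cells)
        ],
        "edges": [
            {"i": int(i), "j": int(j), "l": float(l)}
            for (i, j), l in zip(tissue.edges, tissue.edge_lengths)
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_tissue(path) -> TissueGeometry:
    """Load geometry saved by :func:`save_tissue`; validates invariants."""
    with open(path) as fh:
        payload = json.load(fh)
    cells = payload.get("cells", [])
    if not cells:
        raise ValueError(f"{path}: empty cell list")
    order = [c["id"] for c in cells]
    if sorted(order) != list(range(len(cells))):
        raise ValueError(f"{path}: cell ids must be 0..N-1, got {order[:5]}...")
    by_id = {c["id"]: c for c in cells}
    seen = {}
    edges = []
    lengths = []
    for rec in payload.get("edges", []):
        i, j, l = rec["i"], rec["j"], rec["l"]
        key = (min(i, j), max(i, j))
        if key in seen:
            if seen[key] != l:
                raise ValueError(
                    f"{path}: asymmetric duplicate edge record ({i}, {j})"
                )
            raise ValueError(f"{path}: duplicate edge record ({i}, {j})")
        seen[key] = l
        edges.append(key)
        lengths.append(l)
    n = len(cells)
    order = np.lexsort(
        (np.array([e[1] for e in edges]), np.array([e[0] for e in edges]))
    ) if edges else []
    edges = np.array(edges, dtype=int).reshape(-1, 2)
    return TissueGeometry(
        centroids=np.array([by_id[i]["centroid"] for i in range(n)]),
        polygons=[np.array(by_id[i]["polygon"]) for i in range(n)],
        areas=np.array([by_id[i]["area"] for i in range(n)]),
        edges=edges[order] if len(edges) else edges,
        edge_lengths=np.asarray(lengths)[order] if len(edges) else np.array([]),
    )


@dataclass
class VplcField:
    """Per-cell maximal PLC rates (uM/s) with the initiator mask.

    Initiator cells carry a V_PLC above the single-cell oscillation
    threshold; standby cells sit below it and can only be recruited via
    gap-junction input.
    """

    values: np.ndarray
    initiator_mask: np.ndarray
    seed: object = None
    initiator_range: tuple = None
    standby_range: tuple = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.initiator_mask = np.asarray(self.initiator_mask, dtype=bool)
        if self.values.shape != self.initiator_mask.shape:
            raise ValueError("values and initiator_mask must have the same shape")
        if np.any(self.values < 0):
            raise ValueError("all V_PLC values must be >= 0")

    @property
    def n_initiators(self) -> int:
        return int(self.initiator_mask.sum())

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "cell_id": np.arange(len(self.values)),
                "v_plc": self.values,
                "is_initiator": self.initiator_mask.astype(int),
            }
        ).to_csv(path, index=False)


def assign_vplc(
    tissue: TissueGeometry,
    n_initiators: int,
    initiator_range: tuple[float, float],
    standby_range: tuple[float, float],
    seed=0,
) -> VplcField:
    """Draw a per-cell V_PLC field with ``n_initiators`` initiator cells.

    Initiators are chosen uniformly at random without replacement; their
    V_PLC is uniform on ``initiator_range`` and everyone else's uniform on
    ``standby_range``.  A degenerate range ``[x, x]`` assigns exactly x.
    """
    n = tissue.n_cells
    if not 0 <= n_initiators <= n:
        raise ValueError(f"n_initiators must lie in [0, {n}]")
    for lo, hi in (initiator_range, standby_range):
        if lo > hi or lo < 0:
            raise ValueError(f"invalid V_PLC range [{lo}, {hi}]")
    rng = _as_rng(seed)
    initiators = rng.choice(n, size=n_initiators, replace=False)
    mask = np.zeros(n, dtype=bool)
    mask[initiators] = True
    values = rng.uniform(standby_range[0], standby_range[1], size=n)
    values[mask] = rng.uniform(initiator_range[0], initiator_range[1],
                               size=n_initiators)
    return VplcField(
        values=values,
        initiator_mask=mask,
        seed=seed,
        initiator_range=tuple(initiator_range),
        standby_range=tuple(standby_range),
    )
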