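"""Core containers for skeletonized cell morphologies.

A skeleton is represented as an undirected multigraph whose nodes are
topologically meaningful points (soma, junctions, endpoints) and whose
edges are *branches*: polylines of (row, col) coordinates with a length.
Both the synthetic growth model and the image pipeline produce this
representation, so every downstream metric (branch orders, counts,
lengths, coverage, tiling violations) runs on one data structure.

Conventions
-----------
* Coordinates are (row, col), 0-based, row-major. Ground-truth skeletons
  carry continuous coordinates; image-derived skeletons carry integer
  pixel coordinates.
* Edge data: ``points`` is an (n, 2) float array ordered from node
  ``ends[0]`` to node ``ends[1]``; ``length`` is the sum of Euclidean
  step lengths along the polyline (for pixel polylines this equals the
  1-per-orthogonal / sqrt(2)-per-diagonal step convention).
* Node data: ``pos`` (row, col); ``kind`` in {"soma", "junction",
  "endpoint"}.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import networkx as nx
import numpy as np
from skimage.draw import line as _draw_line

SOMA = "soma"
JUNCTION = "junction"
ENDPOINT = "endpoint"

#: edge identifier inside a CellSkeleton graph: (u, v, key) with u <= v
BranchKey = tuple[int, int, int]


def canonical_key(u: int, v: int, k: int) -> BranchKey:
    return (u, v, k) if u <= v else (v, u, k)


def polyline_length(points: np.ndarray) -> float:
    """Sum of Euclidean step lengths along a polyline of (row, col) points."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        return 0.0
    return float(np.sqrt(((pts[1:] - pts[:-1]) ** 2).sum(axis=1)).sum())


def rasterize_polyline(points: np.ndarray) -> np.ndarray:
    """Round a polyline to pixels, connecting consecutive vertices with
    8-connected Bresenham lines. Returns unique (n, 2) int pixel array in
    traversal order (duplicates removed, first occurrence kept)."""
    pts = np.rint(np.asarray(points, dtype=float)).astype(np.int64)
    if len(pts) == 0:
        return pts.reshape(0, 2)
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    for a, b in zip(pts[:-1], pts[1:]):
        rr, cc = _draw_line(a[0], a[1], b[0], b[1])
        rows.append(rr)
        cols.append(cc)
    if rows:
        rr = np.concatenate(rows)
        cc = np.concatenate(cols)
    else:
        rr = pts[:, 0]
        cc = pts[:, 1]
    pix = np.stack([rr, cc], axis=1)
    # stable de-duplication
    _, idx = np.unique(pix, axis=0, return_index=True)
    return pix[np.sort(idx)]


@dataclass
class CellSkeleton:
    """One cell's branch structure rooted at its soma node.

    Parameters
    ----------
    cell_id : int
        Identifier, unique within a culture / image.
    graph : networkx.MultiGraph
        Branch graph; see module docstring for node/edge attributes.
    soma : int
        Node id of the soma (root).
    """

    cell_id: int
    graph: nx.MultiGraph
    soma: int

    def __post_init__(self) -> None:
        if self.soma not in self.graph:
            raise ValueError(f"soma node {self.soma} not in graph")

    # -- basic accessors -------------------------------------------------
    def branches(self) -> Iterator[tuple[BranchKey, dict]]:
        """Iterate (branch_key, edge_data) in a deterministic order."""
        items = [
            (canonical_key(u, v, k), d)
            for u, v, k, d in self.graph.edges(keys=True, data=True)
        ]
        items.sort(key=lambda t: t[0])
        return iter(items)

    @property
    def n_branches(self) -> int:
        return self.graph.number_of_edges()

    @property
    def total_length(self) -> float:
        return float(sum(d["length"] for _, _, d in self.graph.edges(data=True)))

    @property
    def soma_pos(self) -> tuple[float, float]:
        return tuple(self.graph.nodes[self.soma]["pos"])

    def pixels(self) -> np.ndarray:
        """Unique rasterized pixels of the whole cell (all branch polylines
        plus the soma position), as an (n, 2) int array."""
        parts = [np.rint([self.soma_pos]).astype(np.int64)]
        for _, d in self.branches():
            parts.append(rasterize_polyline(d["points"]))
        allpix = np.concatenate(parts, axis=0)
        return np.unique(allpix, axis=0)

    def branch_pixels(self) -> dict[BranchKey, np.ndarray]:
        """Rasterized pixels per branch."""
        return {key: rasterize_polyline(d["points"]) for key, d in self.branches()}

    def copy(self) -> "CellSkeleton":
        g = nx.MultiGraph()
        g.add_nodes_from((n, dict(d)) for n, d in self.graph.nodes(data=True))
        for u, v, k, d in self.graph.edges(keys=True, data=True):
            d2 = dict(d)
            d2["points"] = np.array(d["points"], copy=True)
            g.add_edge(u, v, key=k, **d2)
        return CellSkeleton(self.cell_id, g, self.soma)


def make_edge(graph: nx.MultiGraph, u: int, v: int, points: np.ndarray) -> BranchKey:
    """Add a branch edge with its orientation recorded; returns its key."""
    points = np.asarray(points, dtype=float)
    k = graph.add_edge(u, v, points=points, length=polyline_length(points), ends=(u, v))
    return canonical_key(u, v, k)


def fuse_degree2_nodes(g: nx.MultiGraph, protect: tuple = ()) -> None:
    """Merge degree-2 nodes (except ``protect``-ed ones) by concatenating
    their two incident branches, in place."""
    changed = True
    while changed:
        changed = False
        for n in sorted(g.nodes):
            if n in protect or g.degree(n) != 2:
                continue
            inc = list(g.edges(n, keys=True, data=True))
            if len(inc) != 2:  # degree-2 via a self-loop: leave alone
                continue
            (u1, v1, k1, d1), (u2, v2, k2, d2) = inc
            if {u1, v1} == {n} or {u2, v2} == {n}:
                continue  # self-loop at n
            # orient each polyline so it ends/starts at n
            p1 = d1["points"] if d1["ends"][1] == n else d1["points"][::-1]
            a = d1["ends"][0] if d1["ends"][1] == n else d1["ends"][1]
            p2 = d2["points"] if d2["ends"][0] == n else d2["points"][::-1]
            b = d2["ends"][1] if d2["ends"][0] == n else d2["ends"][0]
            merged = np.concatenate([p1, p2[1:]], axis=0)
            g.remove_edge(u1, v1, key=k1)
            g.remove_edge(u2, v2, key=k2)
            g.remove_node(n)
            g.add_edge(a, b, points=merged, length=polyline_length(merged), ends=(a, b))
            changed = True
            break


def fuse_passthrough_nodes(cell: CellSkeleton) -> CellSkeleton:
    """Merge degree-2 non-soma nodes of a cell (in place); refresh kinds.

    Used after pruning so that a junction which lost all but one child no
    longer splits what is now a single branch.
    """
    g = cell.graph
    fuse_degree2_nodes(g, protect=(cell.soma,))
    for n, d in g.nodes(data=True):
        if n == cell.soma:
            d["kind"] = SOMA
        elif g.degree(n) >= 3:
            d["kind"] = JUNCTION
        else:
            d["kind"] = ENDPOINT
    return cell
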