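"""Image-to-skeleton-graph pipeline.

Replaces the interactive FIJI workflow (binarize, skeletonize, analyze
skeleton, manual branch-to-cell assignment) with deterministic rules:

1. :func:`binarize` — fixed or Otsu thresholding (strict ``>``).
2. :func:`skeletonize_mask` — homotopic thinning to a 1-pixel-wide,
   8-connected skeleton.
3. :func:`extract_graph` — classify skeleton pixels by 8-neighbour count
   (1 endpoint, 2 path, >= 3 junction), fuse 8-adjacent junction pixels
   into single nodes, and trace branch polylines between nodes. Lengths
   are step sums: 1 per orthogonal step, sqrt(2) per diagonal step.
4. :func:`assign_cells` — snap soma seed coordinates onto the graph and
   assign every branch to the geodesically nearest soma.

Coordinates are 0-based (row, col) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize as _sk_skeletonize

from .skeleton import (
    CellSkeleton,
    ENDPOINT,
    JUNCTION,
    SOMA,
    BranchKey,
    canonical_key,
    polyline_length,
)

_N8 = ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1))

#: kind of the artificial anchor node inserted to represent a pure pixel
#: cycle (a ring with neither endpoints nor junctions) as a self-loop edge
CYCLE = "cycle"


class NonThinSkeletonError(ValueError):
    """Input contains a fully filled 2x2 block, so it is not 1 pixel wide."""


def binarize(
    image: np.ndarray, method: str = "otsu", threshold: float | None = None
) -> np.ndarray:
    """Threshold a grayscale image to a boolean mask (strict ``>``).

    ``method="fixed"`` requires ``threshold``; ``method="otsu"`` derives it
    from a 256-bin histogram and fails on constant images.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if method == "fixed":
        if threshold is None:
            raise ValueError("fixed method requires a threshold")
        thr = float(threshold)
    elif method == "otsu":
        if np.ptp(img) == 0:
            raise ValueError("otsu thresholding is undefined for a constant image")
        thr = float(threshold_otsu(img, nbins=256))
    else:
        raise ValueError(f"unknown binarization method: {method!r}")
    return img > thr


def _square_blocks(mask: np.ndarray) -> np.ndarray:
    """Top-left corners of fully filled 2x2 blocks."""
    return mask[:-1, :-1] & mask[:-1, 1:] & mask[1:, :-1] & mask[1:, 1:]


def _is_simple(mask: np.ndarray, r: int, c: int) -> bool:
    """True when removing pixel (r, c) preserves local 8-connectivity:
    its foreground neighbours form one 8-connected component and there
    are at least two of them (endpoints are never removed)."""
    H, W = mask.shape
    nbrs = [
        (dr, dc)
        for dr, dc in _N8
        if 0 <= r + dr < H and 0 <= c + dc < W and mask[r + dr, c + dc]
    ]
    if len(nbrs) < 2:
        return False
    comp = {nbrs[0]}
    frontier = [nbrs[0]]
    rest = set(nbrs[1:])
    while frontier:
        a = frontier.pop()
        linked = {b for b in rest if max(abs(a[0] - b[0]), abs(a[1] - b[1])) <= 1}
        rest -= linked
        comp |= linked
        frontier.extend(linked)
    return not rest


def skeletonize_mask(mask: np.ndarray) -> np.ndarray:
    """Thin a binary mask to a 1-pixel-wide, 8-connected skeleton.

    Uses homotopic thinning, then removes residual pixels of any fully
    filled 2x2 block whenever deletion preserves local connectivity, so
    the result is safe input for :func:`extract_graph`. Connected-component
    count is preserved and the skeleton is a subset of the mask.
    """
    mask = np.asarray(mask, dtype=bool)
    skel = _sk_skeletonize(mask)
    # clean 2x2 staircase artifacts left by thinning
    while True:
        corners = np.argwhere(_square_blocks(skel))
        if not len(corners):
            break
        removed = False
        for r0, c0 in corners:
            if not (skel[r0, c0] and skel[r0, c0 + 1] and skel[r0 + 1, c0] and skel[r0 + 1, c0 + 1]):
                continue  # block already broken earlier in this pass
            for r, c in ((r0, c0), (r0, c0 + 1), (r0 + 1, c0), (r0 + 1, c0 + 1)):
                if _is_simple(skel, r, c):
                    skel[r, c] = False
                    removed = True
                    break
        if not removed:
            break
    return skel


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    k = np.ones((3, 3), dtype=np.int64)
    k[1, 1] = 0
    return ndimage.convolve(skel.astype(np.int64), k, mode="constant")


@dataclass
class SkeletonGraph:
    """Branch graph of a whole skeleton image (possibly many cells).

    Nodes carry ``pos`` (representative pixel), ``kind`` and ``pixels``
    (all pixels fused into the node); edges carry ``points`` (pixel
    polyline), ``length`` and ``ends``.
    """

    graph: nx.MultiGraph
    shape: tuple[int, int]

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def node_counts(self) -> dict[str, int]:
        out = {ENDPOINT: 0, JUNCTION: 0, SOMA: 0, CYCLE: 0}
        for _, d in self.graph.nodes(data=True):
            out[d["kind"]] += 1
        return out


def extract_graph(skeleton: np.ndarray) -> SkeletonGraph:
    """Trace a 1-pixel-wide skeleton into a branch graph.

    Pixels with one 8-neighbour become endpoints, pixels with three or
    more become junctions (8-adjacent junction pixels are fused into one
    node), and chains of 2-neighbour pixels become branch polylines.
    Isolated pixels become single-node components.
    """
    skel = np.asarray(skeleton, dtype=bool)
    # A filled 2x2 block is tolerated only when it is an irreducible
    # branch crossing (no pixel removable without locally disconnecting
    # an arm); such blocks fuse into one junction node below. Any block
    # with a removable pixel means the input was never properly thinned.
    for r0, c0 in np.argwhere(_square_blocks(skel)):
        if any(
            _is_simple(skel, r, c)
            for r, c in ((r0, c0), (r0, c0 + 1), (r0 + 1, c0), (r0 + 1, c0 + 1))
        ):
            raise NonThinSkeletonError(
                "skeleton contains a reducible filled 2x2 block; run "
                "skeletonize_mask first"
            )
    nbr = _neighbor_counts(skel)
    junction = skel & (nbr >= 3)
    path = skel & (nbr == 2)

    # a path pixel whose both neighbours fall in one junction cluster would
    # create a 2-pixel self-loop; absorb it into the cluster instead
    clusters, _ = ndimage.label(junction, structure=np.ones((3, 3)))
    for r, c in np.argwhere(path):
        cls = set()
        for dr, dc in _N8:
            rr, cc = r + dr, c + dc
            if 0 <= rr < skel.shape[0] and 0 <= cc < skel.shape[1] and skel[rr, cc]:
                cls.add(clusters[rr, cc])
        cls.discard(0)
        if len(cls) == 1:
            nb = [
                (r + dr, c + dc)
                for dr, dc in _N8
                if 0 <= r + dr < skel.shape[0]
                and 0 <= c + dc < skel.shape[1]
                and skel[r + dr, c + dc]
            ]
            if len(nb) == 2 and all(junction[p] for p in nb):
                junction[r, c] = True
                path[r, c] = False
    clusters, n_clusters = ndimage.label(junction, structure=np.ones((3, 3)))

    g = nx.MultiGraph()
    node_of_pixel: dict[tuple[int, int], int] = {}
    next_id = 0

    # junction-cluster nodes (representative = pixel nearest the centroid)
    for ci in range(1, n_clusters + 1):
        pix = np.argwhere(clusters == ci)
        centroid = pix.mean(axis=0)
        d2 = ((pix - centroid) ** 2).sum(axis=1)
        rep = pix[np.lexsort((pix[:, 1], pix[:, 0], d2))[0]]
        g.add_node(
            next_id,
            pos=(int(rep[0]), int(rep[1])),
            kind=JUNCTION,
            pixels=[tuple(p) for p in map(tuple, pix)],
        )
        for p in map(tuple, pix):
            node_of_pixel[p] = next_id
        next_id += 1

    # endpoint and isolated-pixel nodes
    for r, c in np.argwhere(skel & (nbr <= 1)):
        p = (int(r), int(c))
        g.add_node(next_id, pos=p, kind=ENDPOINT, pixels=[p])
        node_of_pixel[p] = next_id
        next_id += 1

    visited = np.zeros_like(skel, dtype=bool)
    direct_pairs: set[frozenset] = set()

    def neighbors(p):
        r, c = p
        for dr, dc in _N8:
            rr, cc = r + dr, c + dc
            if 0 <= rr < skel.shape[0] and 0 <= cc < skel.shape[1] and skel[rr, cc]:
                yield (rr, cc)

    node_pixels = sorted(node_of_pixel)
    for np_ in node_pixels:
        for q in neighbors(np_):
            if q in node_of_pixel:
                a, b = node_of_pixel[np_], node_of_pixel[q]
                if a == b:
                    continue
                pair = frozenset((np_, q))
                if pair in direct_pairs:
                    continue
                direct_pairs.add(pair)
                pts = np.array([np_, q], dtype=float)
                g.add_edge(a, b, points=pts, length=polyline_length(pts), ends=(a, b))
            elif path[q] and not visited[q]:
                poly = [np_, q]
                visited[q] = True
                prev, cur = np_, q
                while True:
                    nxt = next(p for p in neighbors(cur) if p != prev)
                    poly.append(nxt)
                    if nxt in node_of_pixel:
                        b = node_of_pixel[nxt]
                        break
                    visited[nxt] = True
                    prev, cur = cur, nxt
                a = node_of_pixel[np_]
                pts = np.array(poly, dtype=float)
                g.add_edge(a, b, points=pts, length=polyline_length(pts), ends=(a, b))

    # pure cycles: rings of path pixels touching no node
    remaining = path & ~visited
    for r, c in np.argwhere(remaining):
        p = (int(r), int(c))
        if visited[p] or p in node_of_pixel:
            continue
        g.add_node(next_id, pos=p, kind=CYCLE, pixels=[p])
        node_of_pixel[p] = next_id
        start = next_id
        next_id += 1
        nbs = [q for q in neighbors(p)]
        poly = [p, nbs[0]]
        visited[p] = True
        visited[nbs[0]] = True
        prev, cur = p, nbs[0]
        while True:
            nxt = [q for q in neighbors(cur) if q != prev][0]
            poly.append(nxt)
            if nxt == p:
                break
            visited[nxt] = True
            prev, cur = cur, nxt
        pts = np.array(poly, dtype=float)
        g.add_edge(start, start, points=pts, length=polyline_length(pts), ends=(start, start))

    return SkeletonGraph(graph=g, shape=skel.shape)


def prune_short_terminals(sg: SkeletonGraph, min_length: float = 3.0) -> SkeletonGraph:
    """Drop terminal branches shorter than ``min_length`` pixels (the
    deterministic stand-in for manual skeleton cleanup), then fuse the
    pass-through nodes this leaves behind."""
    g = sg.graph
    doomed = []
    for u, v, k, d in g.edges(keys=True, data=True):
        if d["length"] >= min_length:
            continue
        if g.degree(u) == 1 or g.degree(v) == 1:
            doomed.append((u, v, k))
    for u, v, k in doomed:
        g.remove_edge(u, v, key=k)
    g.remove_nodes_from([n for n in list(g.nodes) if g.degree(n) == 0])
    from .skeleton import fuse_degree2_nodes

    fuse_degree2_nodes(g)
    for n, d in g.nodes(data=True):
        d["kind"] = JUNCTION if g.degree(n) >= 3 else ENDPOINT
    return sg


@dataclass
class CellAssignment:
    """Result of :func:`assign_cells`."""

    cells: list[CellSkeleton]
    unassigned: list[BranchKey]
    ambiguous: list[BranchKey]


def assign_cells(
    sg: SkeletonGraph,
    somata: list[tuple[float, float]],
    max_snap: float = 5.0,
) -> CellAssignment:
    """Partition branches among cells by geodesic distance from the somata.

    Each soma coordinate is snapped to the nearest skeleton pixel (a node
    is inserted when it falls mid-branch); every branch then belongs to
    the cell whose soma is geodesically nearest along the graph (distance
    to the branch's nearer end node; ties to the lower cell id, flagged
    ambiguous). Branches unreachable from any soma are reported
    unassigned.
    """
    g = sg.graph
    # snap: nearest pixel over all node and polyline pixels
    pix_list: list[tuple[int, int]] = []
    owner: list[tuple] = []  # ("node", id) or ("edge", (u,v,k), index)
    for n, d in g.nodes(data=True):
        for p in d["pixels"]:
            pix_list.append(p)
            owner.append(("node", n))
    for u, v, k, d in g.edges(keys=True, data=True):
        pts = d["points"].astype(int)
        for i in range(1, len(pts) - 1):
            pix_list.append(tuple(pts[i]))
            owner.append(("edge", (u, v, k), i))
    if not pix_list:
        raise ValueError("empty skeleton graph")
    tree = cKDTree(np.asarray(pix_list, dtype=float))

    soma_nodes: dict[int, int] = {}
    for cid, pos in enumerate(somata):
        dist, idx = tree.query(np.asarray(pos, dtype=float))
        if dist > max_snap:
            raise ValueError(
                f"soma {cid} at {tuple(pos)} is {dist:.1f} px from the skeleton "
                f"(max {max_snap})"
            )
        what = owner[idx]
        if what[0] == "node":
            node = what[1]
        else:
            node = _split_edge(g, what[1], what[2])
        if node in soma_nodes.values():
            raise ValueError(f"two somata snap to the same skeleton node {node}")
        soma_nodes[cid] = node

    # multi-source Dijkstra tracking nearest soma (ties -> lower cell id)
    import heapq

    best: dict[int, tuple[float, int]] = {}
    pq = [(0.0, cid, n) for cid, n in sorted(soma_nodes.items())]
    heapq.heapify(pq)
    while pq:
        d, cid, n = heapq.heappop(pq)
        if n in best and (best[n][0], best[n][1]) <= (d, cid):
            continue
        best[n] = (d, cid)
        for _, v, k, ed in g.edges(n, keys=True, data=True):
            nd = d + ed["length"]
            if v not in best or (nd, cid) < best[v]:
                heapq.heappush(pq, (nd, cid, v))

    assignment: dict[BranchKey, int] = {}
    unassigned: list[BranchKey] = []
    ambiguous: list[BranchKey] = []
    for u, v, k in g.edges(keys=True):
        key = canonical_key(u, v, k)
        cand = [best[n] for n in (u, v) if n in best]
        if not cand:
            unassigned.append(key)
            continue
        dmin = min(c[0] for c in cand)
        cids = sorted({c[1] for c in cand if c[0] == dmin})
        assignment[key] = cids[0]
        if len(cids) > 1:
            ambiguous.append(key)

    cells: list[CellSkeleton] = []
    for cid, soma_node in sorted(soma_nodes.items()):
        sub = nx.MultiGraph()
        for u, v, k, d in g.edges(keys=True, data=True):
            if assignment.get(canonical_key(u, v, k)) == cid:
                for n in (u, v):
                    if n not in sub:
                        sub.add_node(n, **g.nodes[n])
                sub.add_edge(u, v, key=k, **d)
        if soma_node not in sub:
            sub.add_node(soma_node, **g.nodes[soma_node])
        # keep the component containing the soma
        comp = nx.node_connected_component(sub, soma_node)
        for key in [
            canonical_key(u, v, k)
            for u, v, k in sub.edges(keys=True)
            if u not in comp
        ]:
            if assignment.get(key) == cid:
                unassigned.append(key)
        sub = sub.subgraph(comp).copy()
        sub.nodes[soma_node]["kind"] = SOMA
        cells.append(CellSkeleton(cell_id=cid, graph=sub, soma=soma_node))
    return CellAssignment(cells=cells, unassigned=unassigned, ambiguous=ambiguous)


def _split_edge(g: nx.MultiGraph, ukey: tuple, index: int) -> int:
    """Insert a node at polyline position ``index`` of edge ``ukey``."""
    u, v, k = ukey
    d = g.get_edge_data(u, v, k)
    pts = d["points"]
    a, b = d["ends"]
    new = max(g.nodes) + 1
    p = tuple(int(x) for x in pts[index])
    g.add_node(new, pos=p, kind=JUNCTION, pixels=[p])
    g.remove_edge(u, v, key=k)
    left = pts[: index + 1]
    right = pts[index:]
    g.add_edge(a, new, points=left, length=polyline_length(left), ends=(a, new))
    g.add_edge(new, b, points=right, length=polyline_length(right), ends=(new, b))
    return new
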