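"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (enumeration, all-pairs scans) and
shares no code with the package's implementations.
"""

from __future__ import annotations

import numpy as np
import networkx as nx

from astrotile.skeleton import CellSkeleton, SOMA, JUNCTION, ENDPOINT, polyline_length


# ---------------------------------------------------------------------------
# construction helpers
# ---------------------------------------------------------------------------


def make_cell(cell_id: int, soma_pos, branches) -> CellSkeleton:
    """Build a CellSkeleton from explicit polylines.

    ``branches`` is a list of point sequences; endpoints that coincide (to
    1e-9) are merged into shared nodes; the node at ``soma_pos`` is the
    soma.
    """
    g = nx.MultiGraph()
    nodes: dict[tuple, int] = {}

    def node_for(p):
        key = (round(float(p[0]), 9), round(float(p[1]), 9))
        if key not in nodes:
            nodes[key] = len(nodes)
            g.add_node(nodes[key], pos=key, kind=ENDPOINT)
        return nodes[key]

    soma = node_for(soma_pos)
    for pts in branches:
        pts = np.asarray(pts, dtype=float)
        u = node_for(pts[0])
        v = node_for(pts[-1])
        g.add_edge(u, v, points=pts, length=polyline_length(pts), ends=(u, v))
    for n in g.nodes:
        g.nodes[n]["kind"] = (
            SOMA if n == soma else (JUNCTION if g.degree(n) >= 3 else ENDPOINT)
        )
    return CellSkeleton(cell_id=cell_id, graph=g, soma=soma)


# ---------------------------------------------------------------------------
# branch-order oracle: enumerate soma-to-tip paths on a tree
# ---------------------------------------------------------------------------


def tree_orders(cell: CellSkeleton) -> dict:
    """Edge orders by explicit path enumeration (trees only):
    order = 1 + number of junction nodes passed strictly before the edge
    on the unique path from the soma."""
    g = cell.graph
    assert nx.is_tree(nx.Graph(g)) or g.number_of_edges() == 0
    orders = {}
    stack = [(cell.soma, None, 0)]  # node, edge-arrived-by, junctions passed
    while stack:
        node, via, jpassed = stack.pop()
        for u, v, k in g.edges(node, keys=True):
            key = (min(u, v), max(u, v), k)
            if key == via:
                continue
            orders[key] = 1 + jpassed
            nxt_j = jpassed + (1 if g.degree(v) >= 3 else 0)
            stack.append((v, key, nxt_j))
    return orders


def leaf_delete(cell: CellSkeleton, rounds: int) -> int:
    """Iterative leaf deletion on the branch tree; returns the number of
    branches remaining after ``rounds`` rounds of removing every terminal
    branch (soma never removed)."""
    g = nx.MultiGraph(cell.graph)
    for _ in range(rounds):
        doomed = [
            (u, v, k)
            for u, v, k in g.edges(keys=True)
            if (g.degree(u) == 1 and u != cell.soma)
            or (g.degree(v) == 1 and v != cell.soma)
        ]
        g.remove_edges_from(doomed)
        g.remove_nodes_from([n for n in list(g.nodes) if g.degree(n) == 0 and n != cell.soma])
        # fuse chains so next round's "terminal branch" matches the pruned tree
        changed = True
        while changed:
            changed = False
            for n in list(g.nodes):
                if n == cell.soma or g.degree(n) != 2:
                    continue
                inc = list(g.edges(n, keys=True))
                if len(inc) != 2 or any(u == v for u, v, _ in inc):
                    continue
                (u1, v1, k1), (u2, v2, k2) = inc
                a = u1 if v1 == n else v1
                b = u2 if v2 == n else v2
                g.remove_edge(u1, v1, key=k1)
                g.remove_edge(u2, v2, key=k2)
                g.remove_node(n)
                g.add_edge(a, b)
                changed = True
                break
    return g.number_of_edges()


# ---------------------------------------------------------------------------
# skeleton-pixel classification oracle
# ---------------------------------------------------------------------------


def classify_pixels(skel: np.ndarray) -> dict:
    """Brute-force 8-neighbour classification of skeleton pixels.

    Returns endpoint count (exactly 1 neighbour, plus isolated pixels),
    junction cluster count (8-connected components of pixels with >= 3
    neighbours), and edge count (path-pixel chain components attached to
    nodes, plus direct node-node adjacencies, plus pure cycles).
    """
    skel = np.asarray(skel, dtype=bool)
    H, W = skel.shape
    pix = [tuple(p) for p in np.argwhere(skel)]
    pset = set(pix)

    def nbrs(p):
        r, c = p
        return [
            (r + dr, c + dc)
            for dr in (-1, 0, 1)
            for dc in (-1, 0, 1)
            if (dr, dc) != (0, 0) and (r + dr, c + dc) in pset
        ]

    ncount = {p: len(nbrs(p)) for p in pix}
    endpoints = [p for p in pix if ncount[p] <= 1]
    junction_pixels = {p for p in pix if ncount[p] >= 3}
    path_pixels = {p for p in pix if ncount[p] == 2}
    # absorb path pixels whose both neighbours sit in one junction cluster
    jclusters = _components(junction_pixels)
    cluster_of = {}
    for i, comp in enumerate(jclusters):
        for p in comp:
            cluster_of[p] = i
    moved = True
    while moved:
        moved = False
        for p in list(path_pixels):
            nn = nbrs(p)
            cl = {cluster_of.get(q) for q in nn}
            if len(nn) == 2 and None not in cl and len(cl) == 1:
                path_pixels.discard(p)
                junction_pixels.add(p)
                cluster_of[p] = cl.pop()
                moved = True
        if moved:
            jclusters = _components(junction_pixels)
            cluster_of = {}
            for i, comp in enumerate(jclusters):
                for p in comp:
                    cluster_of[p] = i

    node_pixels = junction_pixels | set(endpoints)

    # edges: chain components of path pixels
    chains = _components(path_pixels)
    n_edges = 0
    attached_path = set()
    for comp in chains:
        touches = any(q in node_pixels for p in comp for q in nbrs(p))
        n_edges += 1  # chain = one edge (cycle chains also one self-loop)
        attached_path |= comp
    # direct node-node adjacencies across distinct nodes
    seen_pairs = set()
    node_id = {}
    for i, comp in enumerate(jclusters):
        for p in comp:
            node_id[p] = ("j", i)
    for p in endpoints:
        node_id[p] = ("e", p)
    for p in node_pixels:
        for q in nbrs(p):
            if q in node_pixels and node_id[p] != node_id[q]:
                pair = frozenset((p, q))
                if pair not in seen_pairs:
                    seen_pairs.add(pair)
                    n_edges += 1
    return {
        "endpoints": len(endpoints),
        "junction_clusters": len(jclusters),
        "edges": n_edges,
    }


def _components(points: set) -> list[set]:
    points = set(points)
    comps = []
    while points:
        seed = points.pop()
        comp = {seed}
        frontier = [seed]
        while frontier:
            r, c = frontier.pop()
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    q = (r + dr, c + dc)
                    if q in points:
                        points.discard(q)
                        comp.add(q)
                        frontier.append(q)
        comps.append(comp)
    return comps


# ---------------------------------------------------------------------------
# all-pairs violation oracle
# ---------------------------------------------------------------------------


def brute_force_violations(cells, epsilon: int) -> dict:
    """Per-branch violation flags by exhaustive pixel-pair comparison."""
    flags = {}
    pix_by_cell = {c.cell_id: c.pixels() for c in cells}
    for cell in cells:
        others = [
            pix_by_cell[c.cell_id] for c in cells if c.cell_id != cell.cell_id
        ]
        other = np.concatenate(others) if others else np.empty((0, 2), dtype=int)
        for key, pix in cell.branch_pixels().items():
            if len(other):
                d = np.abs(pix[:, None, :] - other[None, :, :]).max(axis=2)
                flags[(cell.cell_id, key)] = bool((d <= epsilon).any())
            else:
                flags[(cell.cell_id, key)] = False
    return flags
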