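"""Per-cell morphometrics: topological branch orders, branch counts and
lengths, bounding-rectangle coverage, and thresholded marker area/intensity.

The topological branch order of a branch counts how many times the
process has branched between the cell body and that branch: branches
incident to the soma have order 1, and crossing any junction increments
the order by 1. Maximum order and the per-order histogram summarize how
deeply a cell has ramified.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .skeleton import BranchKey, CellSkeleton, canonical_key


@dataclass
class BranchOrders:
    """Per-branch topological orders for one cell.

    ``orders`` maps branch key -> order (soma-incident branches are 1).
    ``cycle_flags`` holds branches that lie on a cycle; such a branch is
    assigned the minimum order over its two approach paths.
    """

    orders: dict[BranchKey, int]
    cycle_flags: set[BranchKey] = field(default_factory=set)

    @property
    def max_order(self) -> int:
        return max(self.orders.values(), default=0)

    def histogram(self) -> np.ndarray:
        """Counts per order, index o-1 for order o (length == max_order)."""
        h = np.zeros(self.max_order, dtype=np.int64)
        for o in self.orders.values():
            h[o - 1] += 1
        return h


def branch_orders(cell: CellSkeleton) -> BranchOrders:
    """Assign topological orders by shortest-path traversal from the soma.

    The traversal is a Dijkstra on nodes where crossing a junction node
    (degree >= 3) costs 1 and passing through any other node costs 0, so
    on trees it reduces to the usual breadth-first order assignment and on
    (rare) cycles every branch receives the minimum order over its
    approach paths.
    """
    g = cell.graph
    if g.number_of_nodes() and not nx.is_connected(g):
        raise ValueError(f"cell {cell.cell_id} is not connected")

    dist: dict[int, int] = {cell.soma: 1}
    orders: dict[BranchKey, int] = {}
    done: set[int] = set()
    pq: list[tuple[int, int]] = [(1, cell.soma)]
    while pq:
        d, u = heapq.heappop(pq)
        if u in done:
            continue
        done.add(u)
        for _, v, k in sorted(g.edges(u, keys=True), key=lambda e: (e[1], e[2])):
            key = canonical_key(u, v, k)
            if key not in orders:
                orders[key] = d
            w = d + (1 if g.degree(v) >= 3 else 0)
            if v not in dist or w < dist[v]:
                dist[v] = w
                heapq.heappush(pq, (w, v))

    # cycle flags: self-loops, parallel edges, and non-bridge edges
    flags: set[BranchKey] = set()
    simple = nx.Graph()
    simple.add_nodes_from(g.nodes)
    pair_count: dict[tuple[int, int], int] = {}
    for u, v, k in g.edges(keys=True):
        key = canonical_key(u, v, k)
        if u == v:
            flags.add(key)
            continue
        pair = (min(u, v), max(u, v))
        pair_count[pair] = pair_count.get(pair, 0) + 1
        simple.add_edge(*pair)
    multi_pairs = {p for p, n in pair_count.items() if n > 1}
    bridges = set() if simple.number_of_edges() == 0 else {
        (min(a, b), max(a, b)) for a, b in nx.bridges(simple)
    }
    for u, v, k in g.edges(keys=True):
        key = canonical_key(u, v, k)
        pair = (min(u, v), max(u, v))
        if u != v and (pair in multi_pairs or pair not in bridges):
            flags.add(key)
    return BranchOrders(orders=orders, cycle_flags=flags)


@dataclass
class CellMetrics:
    """Scalar morphometrics for one cell."""

    cell_id: int
    total_length: float
    branch_count: int
    bounding_rect_area: int
    max_order: int
    order_histogram: np.ndarray

    def __post_init__(self) -> None:
        assert int(self.order_histogram.sum()) == self.branch_count


def cell_metrics(cell: CellSkeleton, orders: BranchOrders | None = None) -> CellMetrics:
    """Branch count, total length, axis-aligned bounding-rectangle area
    (in whole pixels: (max_row - min_row + 1) * (max_col - min_col + 1)),
    and branch-order summaries."""
    if orders is None:
        orders = branch_orders(cell)
    pix = cell.pixels()
    if len(pix) == 0:
        area = 0
    else:
        area = int(
            (pix[:, 0].max() - pix[:, 0].min() + 1)
            * (pix[:, 1].max() - pix[:, 1].min() + 1)
        )
    return CellMetrics(
        cell_id=cell.cell_id,
        total_length=cell.total_length,
        branch_count=cell.n_branches,
        bounding_rect_area=area,
        max_order=orders.max_order,
        order_histogram=orders.histogram(),
    )


def metrics_table(cells: list[CellSkeleton], **labels) -> pd.DataFrame:
    """Tidy per-cell metrics; extra keyword labels (e.g. div=..., condition=...)
    become constant columns."""
    rows = []
    for cell in cells:
        m = cell_metrics(cell)
        rows.append(
            {
                "cell_id": m.cell_id,
                **labels,
                "total_length": m.total_length,
                "branch_count": m.branch_count,
                "bounding_rect_area": m.bounding_rect_area,
                "max_order": m.max_order,
            }
        )
    return pd.DataFrame(rows)


def order_histogram_table(cells: list[CellSkeleton], **labels) -> pd.DataFrame:
    """Long-format branch-order histogram: one row per (cell, order)."""
    rows = []
    for cell in cells:
        h = branch_orders(cell).histogram()
        for o, n in enumerate(h, start=1):
            rows.append({"cell_id": cell.cell_id, **labels, "order": o, "count": int(n)})
    return pd.DataFrame(rows, columns=["cell_id", *labels, "order", "count"])


def marker_area_intensity(
    image: np.ndarray, threshold: float
) -> tuple[int, float]:
    """Marker-positive area and mean intensity above a threshold.

    Returns ``(n_pixels_above, mean_intensity_above)``; the mean is NaN
    when no pixel exceeds the threshold (strict inequality).
    """
    img = np.asarray(image, dtype=float)
    sel = img > threshold
    area = int(sel.sum())
    mean = float(img[sel].mean()) if area else float("nan")
    return area, mean
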