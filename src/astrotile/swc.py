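"""SWC serialization of cell skeletons (one file per cell).

Every polyline vertex becomes an SWC sample, so write -> read reproduces
node coordinates and topology exactly for tree-shaped cells. Type code 1
marks the soma sample, 0 the branch samples. SWC stores (x, y) = (col,
row); conversion happens here and only here. Cycles cannot be expressed
in SWC's parent-pointer tree: the closing link of a cycle edge is
dropped with a warning comment in the file (the CSV edge list emitted by
the CLI is the lossless record for non-tree graphs).
"""

from __future__ import annotations

import re
from pathlib import Path

import networkx as nx
import numpy as np

from .skeleton import CellSkeleton, ENDPOINT, JUNCTION, SOMA, polyline_length

_SOMA_TYPE = 1
_BRANCH_TYPE = 0


def write_cell_swc(cell: CellSkeleton, path: str | Path, radius: float = 0.5) -> None:
    """Write one cell to SWC; floats use shortest round-trip formatting."""
    g = cell.graph
    lines = ["# astrotile SWC export", f"# cell_id {cell.cell_id}"]
    sid = {}  # graph node -> swc id of its sample
    next_id = 1

    def emit(pos, typ, parent):
        nonlocal next_id
        r, c = float(pos[0]), float(pos[1])
        lines.append(
            f"{next_id} {typ} {c!r} {r!r} 0.0 {radius!r} {parent}"
        )
        next_id += 1
        return next_id - 1

    sid[cell.soma] = emit(g.nodes[cell.soma]["pos"], _SOMA_TYPE, -1)
    seen_edges = set()
    stack = [cell.soma]
    dropped = 0
    while stack:
        u = stack.pop()
        for _, v, k, d in sorted(
            g.edges(u, keys=True, data=True), key=lambda e: (e[1], e[2])
        ):
            ek = (min(u, v), max(u, v), k)
            if ek in seen_edges:
                continue
            seen_edges.add(ek)
            pts = d["points"] if d["ends"][0] == u else d["points"][::-1]
            parent = sid[u]
            for p in pts[1:-1]:
                parent = emit(p, _BRANCH_TYPE, parent)
            if v in sid:
                dropped += 1  # cycle-closing link not representable
                if len(pts) > 2:
                    pass
            else:
                sid[v] = emit(pts[-1], _BRANCH_TYPE, parent)
                stack.append(v)
    if dropped:
        lines.insert(2, f"# warning {dropped} cycle-closing links dropped")
    Path(path).write_text("\n".join(lines) + "\n")


def read_cell_swc(path: str | Path, cell_id: int | None = None) -> CellSkeleton:
    """Read an SWC file back into a :class:`CellSkeleton`."""
    path = Path(path)
    if cell_id is None:
        m = re.search(r"(\d+)", path.stem)
        cell_id = int(m.group(1)) if m else 0
    pts: dict[int, tuple[float, float]] = {}
    typ: dict[int, int] = {}
    parent: dict[int, int] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        f = line.split()
        i = int(f[0])
        typ[i] = int(f[1])
        pts[i] = (float(f[3]), float(f[2]))  # (row, col) from (y, x)
        parent[i] = int(f[6])
    roots = [i for i, p in parent.items() if p == -1]
    if len(roots) != 1:
        raise ValueError(f"{path}: expected exactly one root sample, got {len(roots)}")
    root = roots[0]

    children: dict[int, list[int]] = {i: [] for i in pts}
    for i, p in parent.items():
        if p != -1:
            children[p].append(i)

    g = nx.MultiGraph()
    node_of: dict[int, int] = {}
    next_id = 0

    def is_node(i: int) -> bool:
        return i == root or len(children[i]) != 1

    for i in sorted(pts):
        if is_node(i):
            node_of[i] = next_id
            if i == root:
                kind = SOMA
            elif len(children[i]) >= 2:
                kind = JUNCTION
            else:
                kind = ENDPOINT
            g.add_node(next_id, pos=pts[i], kind=kind)
            next_id += 1

    stack = [root]
    while stack:
        start = stack.pop()
        for ch in sorted(children[start]):
            poly = [pts[start]]
            cur = ch
            while not is_node(cur):
                poly.append(pts[cur])
                cur = children[cur][0]
            poly.append(pts[cur])
            pl = np.asarray(poly, dtype=float)
            g.add_edge(
                node_of[start],
                node_of[cur],
                points=pl,
                length=polyline_length(pl),
                ends=(node_of[start], node_of[cur]),
            )
            stack.append(cur)

    return CellSkeleton(cell_id=int(cell_id), graph=g, soma=node_of[root])


def write_culture_swc(cells: list[CellSkeleton], out_dir: str | Path, radius: float = 0.5) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for cell in cells:
        p = out_dir / f"cell_{cell.cell_id:03d}.swc"
        write_cell_swc(cell, p, radius=radius)
        paths.append(p)
    return paths


def read_culture_swc(swc_dir: str | Path) -> list[CellSkeleton]:
    swc_dir = Path(swc_dir)
    files = sorted(swc_dir.glob("*.swc"))
    if not files:
        raise FileNotFoundError(f"no .swc files in {swc_dir}")
    return [read_cell_swc(p) for p in files]
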