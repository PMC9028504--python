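"""Synthetic astrocyte cultures grown by contact-repulsive tip extension.

The generator emulates cultured astrocytes whose branches radiate from a
soma and preferentially extend into space not already occupied by other
astrocyte branches. Each active branch tip proposes a handful of candidate
headings (previous heading plus Gaussian noise); with repulsion enabled, a
candidate is rejected when the new segment would pass within
``avoid_radius`` of another cell's existing branches (and, with
self-avoidance, of the cell's own non-recent branches). A tip with no
acceptable candidate stalls permanently. Tips split into two diverging
tips with probability ``branch_prob`` per step, which is what produces the
deep multi-order branch trees seen in mature tiled cultures.

Named presets:

* ``"tiled-DIV15"`` — repulsion on; a dense, deeply branched culture in
  which territories tile with essentially no contact between cells.
* ``"neutral"`` — same growth with inter-cell repulsion off, so
  territories overlap freely (the untiled control regime).
* ``"sparse-validation"`` — a sparse configuration whose branch spacing
  exceeds typical rendered line widths, for image round-trip validation.

All generators are pure functions of ``(params, seed)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from skimage.morphology import dilation, disk

from .skeleton import CellSkeleton, ENDPOINT, JUNCTION, SOMA, polyline_length

#: reserved value in label images for pixels covered by more than one cell
OVERLAP_LABEL = 65535

#: growth stays this far inside the field border
BOUND_MARGIN = 3.0


class PlacementError(RuntimeError):
    """Raised when somata cannot be placed at the requested spacing."""


class DegenerateGrowthError(RuntimeError):
    """Raised when every tip stalls on the very first step."""


@dataclass(frozen=True)
class GrowthParams:
    """Parameters of the repulsive tip-extension growth model.

    Lengths are in pixel units, angles in radians. Defaults equal the
    ``"tiled-DIV15"`` preset.
    """

    n_cells: int = 9
    field_size: tuple[int, int] = (512, 512)
    soma_min_spacing: float = 130.0
    primaries_per_cell: int = 5
    step_length: float = 2.0
    angle_noise_sd: float = 0.30
    branch_prob: float = 0.25
    divergence_angle: float = 1.2
    avoid_radius: float = 4.0
    self_avoid_radius: float | None = None
    n_candidate_dirs: int = 7
    n_steps: int = 120
    repulsion: bool = True
    self_avoidance: bool = True

    @property
    def effective_self_avoid_radius(self) -> float:
        """Self-avoidance radius; defaults to 0.75 * avoid_radius so that
        sibling branches separated by the divergence angle can coexist."""
        if self.self_avoid_radius is not None:
            return self.self_avoid_radius
        return 0.75 * self.avoid_radius

    def validate(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if min(self.field_size) <= 0:
            raise ValueError("field_size must be positive")
        for name in ("soma_min_spacing", "step_length", "avoid_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.branch_prob <= 1.0:
            raise ValueError("branch_prob must be in [0, 1]")
        if self.n_candidate_dirs < 1:
            raise ValueError("n_candidate_dirs must be >= 1")
        if self.primaries_per_cell < 1:
            raise ValueError("primaries_per_cell must be >= 1")
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")


@dataclass(frozen=True)
class RetractionParams:
    """Excitotoxic-retraction perturbation.

    Each round removes every terminal branch independently with
    ``terminal_prune_prob``; with ``exploration`` on, surviving tips then
    regrow short neutral (non-avoiding) exploratory extensions, emulating
    the wandering processes of astrocytes after neuronal loss.
    """

    terminal_prune_prob: float = 0.5
    n_rounds: int = 2
    exploration: bool = True
    #: probability that a surviving tip explores, and how far it wanders
    explore_prob: float = 0.6
    explore_steps: int = 6

    def validate(self) -> None:
        if not 0.0 <= self.terminal_prune_prob <= 1.0:
            raise ValueError("terminal_prune_prob must be in [0, 1]")
        if self.n_rounds < 0:
            raise ValueError("n_rounds must be >= 0")
        if not 0.0 <= self.explore_prob <= 1.0:
            raise ValueError("explore_prob must be in [0, 1]")


PRESETS: dict[str, GrowthParams] = {
    "tiled-DIV15": GrowthParams(),
    "neutral": GrowthParams(repulsion=False),
    # sparse cultures whose branch spacing exceeds the rendered line
    # width; used to validate the image round trip (render -> binarize ->
    # skeletonize -> extract -> assign) against ground truth
    "sparse-validation": GrowthParams(
        n_cells=3,
        field_size=(300, 300),
        soma_min_spacing=100.0,
        primaries_per_cell=4,
        step_length=2.0,
        angle_noise_sd=0.15,
        branch_prob=0.06,
        divergence_angle=1.2,
        avoid_radius=8.0,
        n_candidate_dirs=7,
        n_steps=80,
    ),
}


@dataclass
class SyntheticCulture:
    """Ground-truth culture: cells, soma positions, and provenance."""

    cells: list[CellSkeleton]
    somata: list[tuple[float, float]]
    provenance: dict
    field_size: tuple[int, int]
    image: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return len(self.cells)


# ---------------------------------------------------------------------------
# growth engine
# ---------------------------------------------------------------------------


class _Tip:
    # anc: ids of the tip's most recent ancestor segments (its own trail),
    # excluded from the self-avoidance test
    __slots__ = ("cell", "node", "heading", "active", "anc")

    def __init__(self, cell: int, node: int, heading: float, anc: np.ndarray | None = None):
        self.cell = cell
        self.node = node
        self.heading = heading
        self.active = True
        self.anc = anc


class _GrowthState:
    """Mutable simulation state; segment geometry lives in flat arrays
    indexed by a uniform spatial hash (see _growth_kernels)."""

    def __init__(self, params: GrowthParams, seed: int):
        params.validate()
        from ._growth_kernels import accept_candidate

        self._accept = accept_candidate
        self.params = params
        self.seed = int(seed)
        self.rng = np.random.Generator(np.random.PCG64(self.seed))
        self.somata = _place_somata(params, self.rng)
        # per-cell raw growth trees (one node per accepted step)
        self.pts: list[list[tuple[float, float]]] = [[s] for s in self.somata]
        self.parent: list[list[int]] = [[-1] for _ in self.somata]
        self.nchild: list[list[int]] = [[0] for _ in self.somata]
        # flat segment store + spatial hash
        cap = 4096
        self.seg = np.empty((cap, 4), dtype=np.float64)
        self.seg_cell = np.empty(cap, dtype=np.int64)
        self.seg_birth = np.empty(cap, dtype=np.int64)
        self.nxt = np.full(cap, -1, dtype=np.int64)
        self.n_seg = 0
        self.hsize = float(params.avoid_radius + params.step_length)
        H, W = params.field_size
        self.head = np.full(
            (int(H // self.hsize) + 2, int(W // self.hsize) + 2), -1, dtype=np.int64
        )
        # self-avoidance ignores own segments younger than the time two
        # diverging siblings need to separate by the self-avoidance radius
        self.r_self = float(params.effective_self_avoid_radius)
        rate = 2.0 * params.step_length * math.sin(max(params.divergence_angle, 1e-6) / 2.0)
        self.grace = max(2, int(math.ceil(self.r_self / max(rate, 1e-9))) + 1)
        # how many trailing ancestor segments a tip is allowed to ignore
        self.n_anc = int(math.ceil(self.r_self / params.step_length)) + 2
        self.tips: list[_Tip] = []
        for ci in range(params.n_cells):
            base = self.rng.uniform(0.0, 2.0 * math.pi)
            for j in range(params.primaries_per_cell):
                h = base + 2.0 * math.pi * j / params.primaries_per_cell
                self.tips.append(_Tip(ci, 0, h, np.full(self.n_anc, -1, dtype=np.int64)))
        self.step = 0

    def _grow_capacity(self) -> None:
        cap = len(self.seg) * 2
        for name in ("seg", "seg_cell", "seg_birth", "nxt"):
            old = getattr(self, name)
            shape = (cap,) + old.shape[1:]
            new = np.full(shape, -1, dtype=old.dtype) if name == "nxt" else np.empty(shape, dtype=old.dtype)
            new[: len(old)] = old
            setattr(self, name, new)

    def _try_extend(self, tip: _Tip) -> bool:
        pr = self.params
        H, W = pr.field_size
        pos = self.pts[tip.cell][tip.node]
        thetas = tip.heading + self.rng.normal(0.0, pr.angle_noise_sd, size=pr.n_candidate_dirs)
        j = self._accept(
            pos[0], pos[1], thetas, pr.step_length, float(H), float(W), BOUND_MARGIN,
            self.seg, self.seg_cell, self.seg_birth, self.head, self.nxt, self.hsize,
            tip.cell, self.step - self.grace, pr.avoid_radius, self.r_self,
            tip.anc, pr.repulsion, pr.self_avoidance,
        )
        if j < 0:
            return False
        theta = float(thetas[j])
        new = (
            pos[0] + pr.step_length * math.sin(theta),
            pos[1] + pr.step_length * math.cos(theta),
        )
        node_idx = len(self.pts[tip.cell])
        self.pts[tip.cell].append(new)
        self.parent[tip.cell].append(tip.node)
        self.nchild[tip.cell].append(0)
        self.nchild[tip.cell][tip.node] += 1
        if self.n_seg >= len(self.seg):
            self._grow_capacity()
        i = self.n_seg
        self.seg[i] = (pos[0], pos[1], new[0], new[1])
        self.seg_cell[i] = tip.cell
        self.seg_birth[i] = self.step
        gr = int((pos[0] + new[0]) * 0.5 // self.hsize)
        gc = int((pos[1] + new[1]) * 0.5 // self.hsize)
        self.nxt[i] = self.head[gr, gc]
        self.head[gr, gc] = i
        self.n_seg += 1
        tip.node = node_idx
        tip.heading = theta
        tip.anc = np.roll(tip.anc, 1)
        tip.anc[0] = i
        return True

    def run_step(self) -> None:
        pr = self.params
        current = [t for t in self.tips if t.active]
        for tip in current:
            if self.rng.random() < pr.branch_prob:
                tip.active = False  # tip becomes a branch point
                for sign in (1.0, -1.0):
                    child = _Tip(
                        tip.cell,
                        tip.node,
                        tip.heading + sign * pr.divergence_angle / 2.0,
                        anc=tip.anc.copy(),
                    )
                    if self._try_extend(child):
                        self.tips.append(child)
            else:
                if not self._try_extend(tip):
                    tip.active = False
        self.step += 1

    def culture(self) -> SyntheticCulture:
        cells = [
            _build_cell_skeleton(ci, self.pts[ci], self.parent[ci], self.nchild[ci])
            for ci in range(self.params.n_cells)
        ]
        prov = {
            "growth": asdict(self.params),
            "seed": self.seed,
            "step": self.step,
        }
        return SyntheticCulture(
            cells=cells,
            somata=list(self.somata),
            provenance=prov,
            field_size=tuple(self.params.field_size),
        )


def _place_somata(params: GrowthParams, rng: np.random.Generator) -> list[tuple[float, float]]:
    H, W = params.field_size
    margin = max(BOUND_MARGIN, 0.09 * min(H, W))
    if H - 2 * margin <= 0 or W - 2 * margin <= 0:
        raise PlacementError("field too small for soma placement margin")
    sp2 = params.soma_min_spacing**2
    for _restart in range(40):
        pos: list[tuple[float, float]] = []
        tries = 0
        while len(pos) < params.n_cells and tries < 400 * params.n_cells:
            tries += 1
            r = rng.uniform(margin, H - 1 - margin)
            c = rng.uniform(margin, W - 1 - margin)
            if all((r - pr) ** 2 + (c - pc) ** 2 >= sp2 for pr, pc in pos):
                pos.append((r, c))
        if len(pos) == params.n_cells:
            return pos
    raise PlacementError(
        f"could not place {params.n_cells} somata at soma_min_spacing="
        f"{params.soma_min_spacing} in field {params.field_size}"
    )


def _build_cell_skeleton(
    cell_id: int,
    pts: Sequence[tuple[float, float]],
    parent: Sequence[int],
    nchild: Sequence[int],
) -> CellSkeleton:
    """Compress the raw growth tree (one node per step) into a branch graph
    whose nodes are the soma, junctions (>= 2 children) and tips."""
    children: list[list[int]] = [[] for _ in pts]
    for i, p in enumerate(parent):
        if p >= 0:
            children[p].append(i)

    g = nx.MultiGraph()
    node_of: dict[int, int] = {}

    def is_node(i: int) -> bool:
        return i == 0 or nchild[i] != 1

    next_id = 0
    for i in range(len(pts)):
        if is_node(i):
            node_of[i] = next_id
            if i == 0:
                kind = SOMA
            elif nchild[i] >= 2:
                kind = JUNCTION
            else:
                kind = ENDPOINT
            g.add_node(next_id, pos=tuple(pts[i]), kind=kind)
            next_id += 1

    # walk chains from every graph node down to the next graph node
    stack = [0]
    while stack:
        start = stack.pop()
        for ch in children[start]:
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

    return CellSkeleton(cell_id, g, node_of[0])


def generate_culture(params: GrowthParams, seed: int) -> SyntheticCulture:
    """Grow one culture; deterministic given ``(params, seed)``."""
    state = _GrowthState(params, seed)
    for _ in range(params.n_steps):
        state.run_step()
        if state.step == 1 and params.n_steps > 0:
            if not any(t.active for t in state.tips) and state.n_seg == 0:
                raise DegenerateGrowthError(
                    "all tips stalled at step 0 (avoid_radius too large for "
                    "this configuration)"
                )
    return state.culture()


def generate_timecourse(
    params: GrowthParams, seed: int, snapshot_steps: Sequence[int]
) -> dict[int, SyntheticCulture]:
    """Grow once, capturing culture snapshots at the given step counts.

    Snapshots share one growth trajectory, so later snapshots extend
    earlier ones — the analogue of imaging the same culture at successive
    days in vitro.
    """
    snaps = sorted(set(int(s) for s in snapshot_steps))
    if any(s < 0 or s > params.n_steps for s in snaps):
        raise ValueError("snapshot steps must lie in [0, n_steps]")
    state = _GrowthState(params, seed)
    out: dict[int, SyntheticCulture] = {}
    if 0 in snaps:
        out[0] = state.culture()
    for _ in range(params.n_steps):
        state.run_step()
        if state.step in snaps:
            out[state.step] = state.culture()
    return out


# ---------------------------------------------------------------------------
# excitotoxic retraction
# ---------------------------------------------------------------------------


def _terminal_branches(cell: CellSkeleton) -> list[tuple]:
    out = []
    for key, d in cell.branches():
        u, v, _ = key
        if (cell.graph.degree(u) == 1 and u != cell.soma) or (
            cell.graph.degree(v) == 1 and v != cell.soma
        ):
            out.append((key, d))
    return out


def apply_retraction(
    culture: SyntheticCulture, rp: RetractionParams, seed: int
) -> SyntheticCulture:
    """Prune terminal branches round-by-round; optionally regrow neutral
    exploratory extensions from surviving tips."""
    rp.validate()
    if not culture.cells:
        raise ValueError("culture has no cells")
    rng = np.random.Generator(np.random.PCG64(int(seed)))
    growth = culture.provenance.get("growth", {})
    step_len = float(growth.get("step_length", 2.0))
    angle_sd = float(growth.get("angle_noise_sd", 0.3))
    H, W = culture.field_size

    from .skeleton import fuse_passthrough_nodes

    new_cells = []
    for cell in culture.cells:
        c = cell.copy()
        for _ in range(rp.n_rounds):
            for (u, v, k), _d in _terminal_branches(c):
                if rng.random() < rp.terminal_prune_prob:
                    c.graph.remove_edge(u, v, key=k)
            for n in [n for n in list(c.graph.nodes) if c.graph.degree(n) == 0 and n != c.soma]:
                c.graph.remove_node(n)
            fuse_passthrough_nodes(c)
        if rp.exploration:
            for n in sorted(c.graph.nodes):
                if n == c.soma or c.graph.degree(n) != 1:
                    continue
                if rng.random() >= rp.explore_prob:
                    continue
                (u, v, k, d) = next(iter(c.graph.edges(n, keys=True, data=True)))
                pts = d["points"] if d["ends"][1] == n else d["points"][::-1]
                pts = list(map(tuple, pts))
                dr = pts[-1][0] - pts[-2][0]
                dc = pts[-1][1] - pts[-2][1]
                heading = math.atan2(dr, dc)
                for _ in range(rp.explore_steps):
                    heading += rng.normal(0.0, angle_sd * 2.0)
                    nr = pts[-1][0] + step_len * math.sin(heading)
                    nc = pts[-1][1] + step_len * math.cos(heading)
                    nr = min(max(nr, BOUND_MARGIN), H - 1 - BOUND_MARGIN)
                    nc = min(max(nc, BOUND_MARGIN), W - 1 - BOUND_MARGIN)
                    pts.append((nr, nc))
                new = np.asarray(pts, dtype=float)
                if d["ends"][1] != n:
                    new = new[::-1]
                d["points"] = new
                d["length"] = polyline_length(new)
                c.graph.nodes[n]["pos"] = tuple(pts[-1])
        new_cells.append(c)

    prov = dict(culture.provenance)
    prov["retraction"] = asdict(rp)
    prov["retraction_seed"] = int(seed)
    return SyntheticCulture(
        cells=new_cells,
        somata=list(culture.somata),
        provenance=prov,
        field_size=culture.field_size,
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def render_image(
    culture: SyntheticCulture,
    line_width: int = 3,
    noise_sd: float = 0.0,
    background: float = 0.0,
    foreground: float = 200.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize a culture to (grayscale image, per-cell label image).

    Branches are drawn ``line_width`` pixels wide (odd widths exact; even
    widths rounded up to the next odd width); the label image is noise
    free and marks pixels covered by more than one cell with
    ``OVERLAP_LABEL``.
    """
    if line_width < 1:
        raise ValueError("line_width must be >= 1")
    H, W = culture.field_size
    labels = np.zeros((H, W), dtype=np.uint16)
    fg = np.zeros((H, W), dtype=bool)
    selem = disk((line_width - 1) // 2) if line_width > 1 else None
    for cell in culture.cells:
        pix = cell.pixels()
        if len(pix) and (
            pix[:, 0].min() < 0 or pix[:, 1].min() < 0
            or pix[:, 0].max() >= H or pix[:, 1].max() >= W
        ):
            raise ValueError(f"cell {cell.cell_id} extends outside the field")
        mask = np.zeros((H, W), dtype=bool)
        mask[pix[:, 0], pix[:, 1]] = True
        if selem is not None:
            mask = dilation(mask, selem)
        fg |= mask
        prev = labels[mask]
        lbl = np.uint16(cell.cell_id + 1)
        labels[mask] = np.where(prev == 0, lbl, np.uint16(OVERLAP_LABEL))
    image = np.full((H, W), float(background), dtype=np.float64)
    image[fg] = float(foreground)
    if noise_sd > 0:
        rng = np.random.Generator(np.random.PCG64(int(seed)))
        image = image + rng.normal(0.0, noise_sd, size=image.shape)
    return image, labels


# ---------------------------------------------------------------------------
# marker-intensity tables
# ---------------------------------------------------------------------------

DEFAULT_MARKERS = ("GLAST", "GLT1", "GAT3", "AQP4")

#: weak (< 0.5) pairwise correlations typical of astrocyte transporter
#: expression heterogeneity; GAT3–AQP4 is a filler value of the same order
DEFAULT_MARKER_CORR = np.array(
    [
        [1.00, 0.23, 0.46, 0.27],
        [0.23, 1.00, 0.46, 0.39],
        [0.46, 0.46, 1.00, 0.30],
        [0.27, 0.39, 0.30, 1.00],
    ]
)
DEFAULT_MARKER_MEANS = (100.0, 120.0, 80.0, 90.0)
DEFAULT_MARKER_CVS = (0.4, 0.4, 0.4, 0.4)


def generate_marker_table(
    n_cells: int,
    target_corr: np.ndarray | None = None,
    means: Sequence[float] | None = None,
    cvs: Sequence[float] | None = None,
    seed: int = 0,
    markers: Sequence[str] | None = None,
    n_images: int = 1,
) -> pd.DataFrame:
    """Correlated lognormal per-cell marker intensities via a Gaussian copula.

    The underlying Gaussian scores have Pearson correlation
    ``target_corr``; marginals are lognormal with the requested means and
    coefficients of variation. Cells are split evenly over ``n_images``
    replicate images (column ``image_id``).
    """
    if target_corr is None:
        target_corr = DEFAULT_MARKER_CORR
    target_corr = np.asarray(target_corr, dtype=float)
    k = target_corr.shape[0]
    if target_corr.shape != (k, k) or not np.allclose(target_corr, target_corr.T):
        raise ValueError("target_corr must be a symmetric square matrix")
    if not np.allclose(np.diag(target_corr), 1.0):
        raise ValueError("target_corr must have unit diagonal")
    w, V = np.linalg.eigh(target_corr)
    if w.min() < -1e-10:
        raise ValueError(
            f"target_corr is not positive semi-definite (min eigenvalue {w.min():.3g})"
        )
    markers = list(markers) if markers is not None else list(DEFAULT_MARKERS[:k])
    if len(markers) != k:
        raise ValueError("markers length must match target_corr size")
    means = np.asarray(means if means is not None else DEFAULT_MARKER_MEANS[:k], dtype=float)
    cvs = np.asarray(cvs if cvs is not None else DEFAULT_MARKER_CVS[:k], dtype=float)
    if means.shape != (k,) or cvs.shape != (k,):
        raise ValueError("means and cvs must have one value per marker")
    if np.any(means <= 0) or np.any(cvs <= 0):
        raise ValueError("means and cvs must be positive")

    L = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    rng = np.random.Generator(np.random.PCG64(int(seed)))
    z = rng.standard_normal((int(n_cells), k)) @ L.T
    sigma = np.sqrt(np.log1p(cvs**2))
    mu = np.log(means) - 0.5 * sigma**2
    x = np.exp(mu + sigma * z)
    df = pd.DataFrame(x, columns=markers)
    df.insert(0, "image_id", np.arange(int(n_cells)) % int(n_images))
    df.insert(0, "cell_id", np.arange(int(n_cells)))
    return df
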