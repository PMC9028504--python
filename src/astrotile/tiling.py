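"""Tiling-violation detection and summaries.

A branch of one cell *violates the tiling* when any of its skeleton
pixels lies within Chebyshev distance epsilon of a pixel belonging to a
different cell. With the default epsilon = 1 this means overlap or
8-adjacency — branches that touch or override another astrocyte's
branches. Self-overlaps (a cell's branch passing close to a non-adjacent
branch of the same cell) are counted separately and excluded from the
between-cell tiling statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter

from .skeleton import CellSkeleton


@dataclass
class ViolationReport:
    """Branch-level flags plus per-cell and per-culture summaries.

    ``branch_table`` columns: cell_id, branch, violating, partners (tuple
    of other-cell ids), self_overlap. ``cell_table`` columns: cell_id,
    branch_count, violating_count, violation_percentage,
    self_overlap_count. ``summary``: culture-level aggregates.
    """

    branch_table: pd.DataFrame
    cell_table: pd.DataFrame
    summary: dict
    epsilon: int


def detect_violations(cells: list[CellSkeleton], epsilon: int = 1) -> ViolationReport:
    """Flag branches that touch or override branches of other cells.

    Detection is symmetric: if a branch of cell A is within epsilon of
    cell B's pixels, at least one branch of B is flagged against A.
    """
    epsilon = int(epsilon)
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    ids = [c.cell_id for c in cells]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate cell ids")

    all_pix = [c.pixels() for c in cells]
    nonempty = [p for p in all_pix if len(p)]
    if not nonempty:
        return _empty_report(epsilon)
    lo = np.min([p.min(axis=0) for p in nonempty], axis=0)
    hi = np.max([p.max(axis=0) for p in nonempty], axis=0)
    pad = epsilon + 1
    shape = (int(hi[0] - lo[0]) + 1 + 2 * pad, int(hi[1] - lo[1]) + 1 + 2 * pad)
    off = lo - pad  # pixel (r, c) -> array index (r - off[0], c - off[1])

    masks = np.zeros((len(cells),) + shape, dtype=bool)
    for i, p in enumerate(all_pix):
        if len(p):
            masks[i, p[:, 0] - off[0], p[:, 1] - off[1]] = True
    if epsilon > 0:
        near = np.stack([maximum_filter(m, size=2 * epsilon + 1) for m in masks])
    else:
        near = masks

    drs, dcs = np.meshgrid(
        np.arange(-epsilon, epsilon + 1), np.arange(-epsilon, epsilon + 1), indexing="ij"
    )
    drs = drs.ravel()
    dcs = dcs.ravel()

    branch_rows = []
    for i, cell in enumerate(cells):
        bp = cell.branch_pixels()
        keys = list(bp)
        # same-cell ownership image: branch index, -1 empty, -2 shared
        owner = np.full(shape, -1, dtype=np.int64)
        multi: dict[tuple[int, int], set[int]] = {}
        for b, key in enumerate(keys):
            pix = bp[key]
            rr = pix[:, 0] - off[0]
            cc = pix[:, 1] - off[1]
            cur = owner[rr, cc]
            fresh = cur == -1
            owner[rr[fresh], cc[fresh]] = b
            for r, c, prev in zip(rr[~fresh], cc[~fresh], cur[~fresh]):
                s = multi.setdefault((int(r), int(c)), set())
                if prev >= 0:
                    s.add(int(prev))
                s.add(b)
                owner[r, c] = -2

        nodesets = [set(key[:2]) for key in keys]
        for b, key in enumerate(keys):
            pix = bp[key]
            rr = pix[:, 0] - off[0]
            cc = pix[:, 1] - off[1]
            hit = near[:, rr, cc].any(axis=1)
            partners = tuple(
                cells[j].cell_id for j in np.flatnonzero(hit) if j != i
            )
            neigh = owner[rr[:, None] + drs[None, :], cc[:, None] + dcs[None, :]]
            uniq = np.unique(neigh)
            owners: set[int] = {int(u) for u in uniq if u >= 0}
            if -2 in uniq:
                sh = np.argwhere(neigh == -2)
                for pi, oi in sh:
                    owners |= multi[(int(rr[pi] + drs[oi]), int(cc[pi] + dcs[oi]))]
            self_ov = any(
                ob != b and not (nodesets[ob] & nodesets[b]) for ob in owners
            )
            branch_rows.append(
                {
                    "cell_id": cell.cell_id,
                    "branch": key,
                    "violating": len(partners) > 0,
                    "partners": partners,
                    "self_overlap": bool(self_ov),
                }
            )

    branch_table = pd.DataFrame(
        branch_rows,
        columns=["cell_id", "branch", "violating", "partners", "self_overlap"],
    )
    cell_rows = []
    for cell in cells:
        sub = branch_table[branch_table["cell_id"] == cell.cell_id]
        n = len(sub)
        v = int(sub["violating"].sum())
        cell_rows.append(
            {
                "cell_id": cell.cell_id,
                "branch_count": n,
                "violating_count": v,
                "violation_percentage": 100.0 * v / n if n else 0.0,
                "self_overlap_count": int(sub["self_overlap"].sum()),
            }
        )
    cell_table = pd.DataFrame(cell_rows)
    return ViolationReport(
        branch_table, cell_table, _summarize(cell_table, epsilon), epsilon
    )


def _empty_report(epsilon: int) -> ViolationReport:
    empty = pd.DataFrame(
        columns=["cell_id", "branch", "violating", "partners", "self_overlap"]
    )
    cellt = pd.DataFrame(
        columns=[
            "cell_id",
            "branch_count",
            "violating_count",
            "violation_percentage",
            "self_overlap_count",
        ]
    )
    return ViolationReport(empty, cellt, _summarize(cellt, epsilon), epsilon)


def _summarize(cell_table: pd.DataFrame, epsilon: int) -> dict:
    n = len(cell_table)
    if n == 0:
        return {
            "n_cells": 0,
            "epsilon": epsilon,
            "mean_violation_percentage": 0.0,
            "mean_violating_count": 0.0,
            "pct_cells_with_violation": 0.0,
        }
    return {
        "n_cells": int(n),
        "epsilon": epsilon,
        "mean_violation_percentage": float(cell_table["violation_percentage"].mean()),
        "mean_violating_count": float(cell_table["violating_count"].mean()),
        "pct_cells_with_violation": float(
            100.0 * (cell_table["violating_count"] > 0).mean()
        ),
    }


def violation_timecourse(reports: dict[object, ViolationReport]) -> pd.DataFrame:
    """Per-timepoint mean +/- s.e.m. of per-cell violation percentages and
    violating-branch counts. Keys of ``reports`` label the timepoints."""
    if not reports:
        raise ValueError("need at least one timepoint")
    rows = []
    for label, rep in reports.items():
        pct = rep.cell_table["violation_percentage"].to_numpy(dtype=float)
        cnt = rep.cell_table["violating_count"].to_numpy(dtype=float)
        n = len(pct)
        rows.append(
            {
                "timepoint": label,
                "n_cells": n,
                "mean_violation_pct": float(pct.mean()) if n else 0.0,
                "sem_violation_pct": float(pct.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
                "mean_violating_count": float(cnt.mean()) if n else 0.0,
                "sem_violating_count": float(cnt.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "timepoint",
            "n_cells",
            "mean_violation_pct",
            "sem_violation_pct",
            "mean_violating_count",
            "sem_violating_count",
        ],
    )
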