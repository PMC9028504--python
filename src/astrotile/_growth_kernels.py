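"""Numba kernels for the growth engine's segment-proximity queries.

Segments live in flat arrays; a uniform spatial hash over segment
midpoints (dense ``head`` grid + ``nxt`` linked list) supports the
candidate-rejection test. The hash cell size must be at least
``avoid_radius + step_length`` so a 3x3 neighbourhood of the candidate's
midpoint cell covers every segment that could lie within
``avoid_radius`` of the candidate segment.
"""

from __future__ import annotations

import math

import numba as nb


@nb.njit(inline="always")
def _point_seg_dist(pr, pc, ar, ac, br, bc):
    dr = br - ar
    dc = bc - ac
    L2 = dr * dr + dc * dc
    if L2 <= 0.0:
        return math.hypot(pr - ar, pc - ac)
    t = ((pr - ar) * dr + (pc - ac) * dc) / L2
    if t < 0.0:
        t = 0.0
    elif t > 1.0:
        t = 1.0
    return math.hypot(pr - (ar + t * dr), pc - (ac + t * dc))


@nb.njit(inline="always")
def _orient(ar, ac, br, bc, cr, cc):
    return (br - ar) * (cc - ac) - (bc - ac) * (cr - ar)


@nb.njit(inline="always")
def _seg_seg_dist(p1r, p1c, q1r, q1c, p2r, p2c, q2r, q2c):
    d1 = _orient(p2r, p2c, q2r, q2c, p1r, p1c)
    d2 = _orient(p2r, p2c, q2r, q2c, q1r, q1c)
    d3 = _orient(p1r, p1c, q1r, q1c, p2r, p2c)
    d4 = _orient(p1r, p1c, q1r, q1c, q2r, q2c)
    if ((d1 > 0.0) != (d2 > 0.0)) and ((d3 > 0.0) != (d4 > 0.0)):
        return 0.0
    m = _point_seg_dist(p1r, p1c, p2r, p2c, q2r, q2c)
    m2 = _point_seg_dist(q1r, q1c, p2r, p2c, q2r, q2c)
    if m2 < m:
        m = m2
    m2 = _point_seg_dist(p2r, p2c, p1r, p1c, q1r, q1c)
    if m2 < m:
        m = m2
    m2 = _point_seg_dist(q2r, q2c, p1r, p1c, q1r, q1c)
    if m2 < m:
        m = m2
    return m


@nb.njit(inline="always")
def _blocked(
    pr, pc, qr, qc, seg, seg_cell, seg_birth, head, nxt, hsize,
    cell, cutoff, avoid, r_self, skip, repulsion, self_av,
):
    gr = int(((pr + qr) * 0.5) // hsize)
    gc = int(((pc + qc) * 0.5) // hsize)
    nrows, ncols = head.shape
    for dr in range(-1, 2):
        rr = gr + dr
        if rr < 0 or rr >= nrows:
            continue
        for dc in range(-1, 2):
            cc = gc + dc
            if cc < 0 or cc >= ncols:
                continue
            i = head[rr, cc]
            while i >= 0:
                sc = seg_cell[i]
                if sc == cell:
                    if (not self_av) or seg_birth[i] > cutoff:
                        i = nxt[i]
                        continue
                    own = False
                    for s in range(skip.shape[0]):
                        if skip[s] == i:
                            own = True
                            break
                    if own:
                        i = nxt[i]
                        continue
                    lim = r_self
                else:
                    if not repulsion:
                        i = nxt[i]
                        continue
                    lim = avoid
                d = _seg_seg_dist(
                    pr, pc, qr, qc, seg[i, 0], seg[i, 1], seg[i, 2], seg[i, 3]
                )
                if d < lim:
                    return True
                i = nxt[i]
    return False


@nb.njit(cache=False)
def accept_candidate(
    pr, pc, thetas, step_len, H, W, margin,
    seg, seg_cell, seg_birth, head, nxt, hsize,
    cell, cutoff, avoid, r_self, skip, repulsion, self_av,
):
    """Return the index of the first acceptable candidate heading, or -1.

    ``skip`` holds ids of the tip's most recent ancestor segments, which
    are exempt from the self-avoidance test (a branch cannot avoid the
    trail it is itself extending)."""
    for j in range(thetas.shape[0]):
        th = thetas[j]
        qr = pr + step_len * math.sin(th)
        qc = pc + step_len * math.cos(th)
        if qr < margin or qr > H - 1.0 - margin:
            continue
        if qc < margin or qc > W - 1.0 - margin:
            continue
        if not _blocked(
            pr, pc, qr, qc, seg, seg_cell, seg_birth, head, nxt, hsize,
            cell, cutoff, avoid, r_self, skip, repulsion, self_av,
        ):
            return j
    return -1
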