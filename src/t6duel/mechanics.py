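"""Capsule contact geometry and quasi-static mechanical relaxation.

Cells are rigid planar capsules (spherocylinders squashed into z = 0).  After
growth and division the configuration is returned to a quasi-stationary
mechanical equilibrium: overlapping contacts are found, a contact Jacobian A
is assembled (one row per overlap, columns over each body's planar degrees
of freedom x, y, theta), and a regularized least-squares system

    (A^T A + alpha * M) p = -A^T d

is solved for pose increments p, where d holds the (negative) contact gaps
and M is a diagonal drag matrix penalizing movement of long (high-drag)
cells.  Applying p shrinks all overlaps toward zero while minimizing total
weighted displacement; the solve is iterated with contacts re-found until
the deepest residual overlap is below ``relax_tol``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial import cKDTree

from .world import Cell, PatchState

__all__ = [
    "Contact",
    "seg_seg_closest",
    "capsule_capsule_distance",
    "find_contacts",
    "contact_arrays",
    "relax",
]

log = logging.getLogger(__name__)

_PARALLEL_TOL = 1e-9


def seg_seg_closest(P1, D1, P2, D2):
    """Closest points between segment pairs, vectorized.

    Segments are ``P + s*D`` for s in [0, 1].  Returns ``(s, t, C1, C2,
    dist)`` where C1/C2 are the witness points.  Near-parallel overlapping
    pairs are tie-broken at the midpoint of the overlap interval, which is
    symmetric and deterministic.
    """
    P1 = np.atleast_2d(np.asarray(P1, float))
    D1 = np.atleast_2d(np.asarray(D1, float))
    P2 = np.atleast_2d(np.asarray(P2, float))
    D2 = np.atleast_2d(np.asarray(D2, float))

    a = np.einsum("ij,ij->i", D1, D1)
    e = np.einsum("ij,ij->i", D2, D2)
    r = P1 - P2
    b = np.einsum("ij,ij->i", D1, D2)
    c = np.einsum("ij,ij->i", D1, r)
    f = np.einsum("ij,ij->i", D2, r)

    eps = 1e-14
    denom = a * e - b * b
    a_safe = np.where(a > eps, a, 1.0)
    e_safe = np.where(e > eps, e, 1.0)
    denom_safe = np.where(denom > eps, denom, 1.0)

    # general skew case
    s = np.clip((b * f - c * e) / denom_safe, 0.0, 1.0)

    # near-parallel: midpoint of the projected overlap interval
    parallel = denom <= _PARALLEL_TOL * np.maximum(a * e, eps)
    if np.any(parallel):
        t0 = -c / a_safe                 # param of P2 on segment 1
        t1 = (b - c) / a_safe            # param of P2+D2 on segment 1
        lo = np.minimum(t0, t1)
        hi = np.maximum(t0, t1)
        lo_c = np.maximum(lo, 0.0)
        hi_c = np.minimum(hi, 1.0)
        has_overlap = lo_c <= hi_c
        s_par = np.where(has_overlap, 0.5 * (lo_c + hi_c),
                         np.clip(0.5 * (lo + hi), 0.0, 1.0))
        s = np.where(parallel, s_par, s)

    t = (b * s + f) / e_safe
    t_cl = np.clip(t, 0.0, 1.0)
    moved = t != t_cl
    s = np.where(moved, np.clip((b * t_cl - c) / a_safe, 0.0, 1.0), s)
    t = t_cl

    # degenerate (point) segments
    s = np.where(a <= eps, 0.0, s)
    t = np.where(e <= eps, 0.0, t)
    t = np.where((a <= eps) & (e > eps), np.clip(f / e_safe, 0.0, 1.0), t)
    s = np.where((e <= eps) & (a > eps), np.clip(-c / a_safe, 0.0, 1.0), s)

    C1 = P1 + s[:, None] * D1
    C2 = P2 + t[:, None] * D2
    dist = np.linalg.norm(C1 - C2, axis=1)
    return s, t, C1, C2, dist


@dataclass
class Contact:
    """A resolved capsule-capsule contact (or near-contact).

    ``d`` is the signed surface gap (negative = overlap); ``normal`` points
    from cell i toward cell j.
    """

    cell_i: int
    cell_j: int
    d: float
    point_i: np.ndarray
    point_j: np.ndarray
    normal: np.ndarray


def _segments(patch: PatchState):
    half = (patch.axis * patch.seg_length[:, None]) / 2.0
    P = patch.center - half
    D = patch.axis * patch.seg_length[:, None]
    return P, D


def capsule_capsule_distance(cell_a: Cell, cell_b: Cell, radius: float | None = None) -> Contact:
    """Signed gap and witness points between two capsule cells.

    Exact for skew, parallel and degenerate (spherical) segments.  For
    coincident segments the witness pair falls at the segment midpoints.
    """
    Ra = radius if radius is not None else _cell_radius(cell_a)
    Rb = radius if radius is not None else _cell_radius(cell_b)
    p1 = (np.asarray(cell_a.center, float) - np.asarray(cell_a.axis, float) * cell_a.seg_length / 2)[None]
    d1 = (np.asarray(cell_a.axis, float) * cell_a.seg_length)[None]
    p2 = (np.asarray(cell_b.center, float) - np.asarray(cell_b.axis, float) * cell_b.seg_length / 2)[None]
    d2 = (np.asarray(cell_b.axis, float) * cell_b.seg_length)[None]
    _, _, c1, c2, dist = seg_seg_closest(p1, d1, p2, d2)
    dvec = c2[0] - c1[0]
    nrm = np.linalg.norm(dvec)
    if nrm > 1e-12:
        normal = dvec / nrm
    else:
        # coincident axes: push apart along any planar direction
        perp = np.array([-cell_a.axis[1], cell_a.axis[0], 0.0])
        normal = perp / max(np.linalg.norm(perp), 1e-12)
    gap = float(dist[0] - (Ra + Rb))
    pi = c1[0] + normal * Ra
    pj = c2[0] - normal * Rb
    return Contact(cell_a.id, cell_b.id, gap, pi, pj, normal)


def _cell_radius(cell: Cell) -> float:
    # Cell views do not carry SimParams, so recover the radius from
    # volume = pi r^2 L + (4/3) pi r^3 (single positive root).
    L, V = cell.seg_length, cell.volume
    roots = np.roots([(4.0 / 3.0) * math.pi, math.pi * L, 0.0, -V])
    real = roots[np.isreal(roots)].real
    pos = real[real > 1e-9]
    return float(pos.max()) if pos.size else 0.5


def contact_arrays(patch: PatchState, cutoff: float):
    """All pairs with surface gap < cutoff, as index/geometry arrays.

    Broad phase: a cKDTree over capsule midpoints queried at the largest
    possible interacting distance, then exact segment-segment narrow phase.
    Returns ``(i, j, gap, point_i, point_j, normal)`` with i < j.
    """
    n = patch.n_cells
    R = patch.params.R_cell
    if n < 2:
        empty = np.empty(0, int)
        return empty, empty, np.empty(0), np.empty((0, 3)), np.empty((0, 3)), np.empty((0, 3))
    tree = cKDTree(patch.center[:, :2])
    reach = float(np.max(patch.seg_length)) + 2 * R + max(cutoff, 0.0) + 1e-9
    pairs = tree.query_pairs(r=reach, output_type="ndarray")
    if pairs.size == 0:
        empty = np.empty(0, int)
        return empty, empty, np.empty(0), np.empty((0, 3)), np.empty((0, 3)), np.empty((0, 3))
    i, j = pairs[:, 0], pairs[:, 1]
    P, D = _segments(patch)
    _, _, c1, c2, dist = seg_seg_closest(P[i], D[i], P[j], D[j])
    gap = dist - 2 * R
    keep = gap < cutoff
    i, j, c1, c2, dist, gap = i[keep], j[keep], c1[keep], c2[keep], dist[keep], gap[keep]
    dvec = c2 - c1
    nrm = np.linalg.norm(dvec, axis=1)
    ok = nrm > 1e-12
    normal = np.zeros_like(dvec)
    normal[ok] = dvec[ok] / nrm[ok, None]
    if np.any(~ok):
        # coincident witness points: use a perpendicular of cell i's axis
        ax = patch.axis[i[~ok]]
        perp = np.stack([-ax[:, 1], ax[:, 0], np.zeros(ax.shape[0])], axis=1)
        normal[~ok] = perp / np.linalg.norm(perp, axis=1)[:, None]
    point_i = c1 + normal * R
    point_j = c2 - normal * R
    return i, j, gap, point_i, point_j, normal


def find_contacts(patch: PatchState, cutoff: float = 0.0) -> list[Contact]:
    """List of :class:`Contact` records with gap < cutoff (i < j)."""
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    i, j, gap, pi, pj, nrm = contact_arrays(patch, cutoff)
    ids = patch.ids
    return [
        Contact(int(ids[a]), int(ids[b]), float(g), pi[k], pj[k], nrm[k])
        for k, (a, b, g) in enumerate(zip(i, j, gap))
    ]


def _drag_matrix(patch: PatchState) -> np.ndarray:
    """Diagonal drag entries for (x, y, theta) per cell; drag grows with length."""
    span = patch.seg_length + 2 * patch.params.R_cell
    m = patch.params.drag_coeff * span
    m_rot = m * (span**2 / 12.0)
    diag = np.empty(3 * patch.n_cells)
    diag[0::3] = m
    diag[1::3] = m
    diag[2::3] = m_rot
    return diag


def _apply_pose_increments(patch: PatchState, p: np.ndarray) -> None:
    dx = p[0::3]
    dy = p[1::3]
    dth = p[2::3]
    patch.center[:, 0] += dx
    patch.center[:, 1] += dy
    patch.center[:, 2] = 0.0
    cos, sin = np.cos(dth), np.sin(dth)
    ax, ay = patch.axis[:, 0].copy(), patch.axis[:, 1].copy()
    patch.axis[:, 0] = cos * ax - sin * ay
    patch.axis[:, 1] = sin * ax + cos * ay
    patch.axis[:, 2] = 0.0
    norm = np.linalg.norm(patch.axis[:, :2], axis=1)
    patch.axis[:, :2] /= norm[:, None]


def relax(patch: PatchState) -> PatchState:
    """Iterate regularized least-squares solves until overlaps clear.

    Pure function of the patch (no RNG draws).  Modifies poses in place and
    returns the patch.  On a singular system the regularization weight is
    escalated tenfold and the solve retried.
    """
    params = patch.params
    n = patch.n_cells
    if n == 0:
        return patch
    max_disp = 1.5 * params.R_cell  # per-cell, per-iteration displacement cap

    for _ in range(params.relax_max_iter):
        i, j, gap, pi, pj, nrm = contact_arrays(patch, cutoff=0.0)
        if gap.size == 0 or float(-gap.min()) < params.relax_tol:
            break
        nc = gap.size
        ri = pi - patch.center[i]
        rj = pj - patch.center[j]
        lever_i = ri[:, 0] * nrm[:, 1] - ri[:, 1] * nrm[:, 0]  # (r x n)_z
        lever_j = rj[:, 0] * nrm[:, 1] - rj[:, 1] * nrm[:, 0]
        rows = np.repeat(np.arange(nc), 6)
        cols = np.empty(6 * nc, dtype=np.int64)
        vals = np.empty(6 * nc)
        cols[0::6], vals[0::6] = 3 * i + 0, -nrm[:, 0]
        cols[1::6], vals[1::6] = 3 * i + 1, -nrm[:, 1]
        cols[2::6], vals[2::6] = 3 * i + 2, -lever_i
        cols[3::6], vals[3::6] = 3 * j + 0, nrm[:, 0]
        cols[4::6], vals[4::6] = 3 * j + 1, nrm[:, 1]
        cols[5::6], vals[5::6] = 3 * j + 2, lever_j
        A = sp.csr_matrix((vals, (rows, cols)), shape=(nc, 3 * n))
        M = _drag_matrix(patch)
        alpha = params.alpha
        rhs = -A.T @ gap
        p = None
        for _try in range(4):
            lhs = (A.T @ A + sp.diags(alpha * M)).tocsc()
            try:
                p = spla.spsolve(lhs, rhs)
                if np.all(np.isfinite(p)):
                    break
            except RuntimeError:
                pass
            log.warning("singular relaxation system; raising alpha to %g", alpha * 10)
            alpha *= 10
        if p is None or not np.all(np.isfinite(p)):
            raise RuntimeError("mechanical relaxation failed to solve")
        worst = float(np.max(np.hypot(p[0::3], p[1::3]))) if n else 0.0
        if worst > max_disp:
            p = p * (max_disp / worst)
        _apply_pose_increments(patch, p)
    return patch
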