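"""T6SS firing, two-step hit detection, intoxication and lysis bookkeeping.

Needles are straight segments of length ``L_needle`` launched in the plane
from a cell's surface.  Random (R-type) strategists fire Poisson(k_fire*dt)
needles per step from uniformly random perimeter points along the outward
surface normal; retaliators answer each queued incoming hit with
``retaliation_multiplicity`` needles from the recorded entry point along the
reversed attack direction (or, for the aiming knockout, from random
perimeter points).  Hit detection is two-step: a candidate test on the
minimum needle-axis distance (< R - L_penetration), then the entry point as
the nearest intersection of the needle with the target capsule surface; a
needle stops at the first cell it enters.

Intoxication is genotype-based: hits from non-clonemates that are not
covered by the target's immunity set increment a cumulative translocation
count; at ``N_hits`` the cell commits to lysis and is removed after a delay
1/k_lysis.  Any non-clonemate hit on a live retaliator (toxic or not) queues
a retaliation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .world import PatchState

__all__ = [
    "Needle",
    "HitRecord",
    "schedule_firings",
    "schedule_all_firings",
    "detect_hits",
    "apply_intoxication",
    "remove_lysed",
    "surface_points",
]


@dataclass
class Needle:
    """One firing event: an oriented segment anchored on the source surface."""

    source_id: int
    origin: np.ndarray
    direction: np.ndarray
    length: float
    step_index: int = 0


@dataclass
class HitRecord:
    """A resolved needle strike on a target cell."""

    needle: Needle
    target_id: int
    entry_point: np.ndarray
    clonemate: bool
    intoxicating: bool = field(default=False)


# ---------------------------------------------------------------------------
# needle origins on the capsule outline
# ---------------------------------------------------------------------------


def surface_points(center, axis, seg_length, radius, u):
    """Map uniform draws u in [0,1) to points on the planar capsule outline.

    Returns (points, outward_normals).  The outline consists of two straight
    flanks of length ``seg_length`` and two semicircular caps; sampling is
    uniform in arc length, so firing direction (the outward normal) is
    uniform over the cell boundary.
    """
    center = np.atleast_2d(center)
    axis = np.atleast_2d(axis)
    seg_length = np.atleast_1d(np.asarray(seg_length, float))
    u = np.atleast_1d(np.asarray(u, float))
    perim = 2 * seg_length + 2 * math.pi * radius
    arc = u * perim
    perp = np.stack([-axis[:, 1], axis[:, 0], np.zeros(len(axis))], axis=1)

    pts = np.empty_like(center)
    nrm = np.empty_like(center)

    # piece boundaries: flank+ [0, L), cap+ [L, L+piR), flank- , cap-
    L = seg_length
    cap = math.pi * radius
    a1, a2, a3 = L, L + cap, 2 * L + cap

    m = arc < a1
    if m.any():
        s = arc[m] - L[m] / 2
        pts[m] = center[m] + axis[m] * s[:, None] + perp[m] * radius
        nrm[m] = perp[m]
    m = (arc >= a1) & (arc < a2)
    if m.any():
        phi = (arc[m] - a1[m]) / radius  # 0..pi, from +perp side to -perp side
        tip = center[m] + axis[m] * (L[m] / 2)[:, None]
        n = (
            np.cos(phi)[:, None] * perp[m]
            + np.sin(phi)[:, None] * axis[m]
        )
        pts[m] = tip + n * radius
        nrm[m] = n
    m = (arc >= a2) & (arc < a3)
    if m.any():
        s = (arc[m] - a2[m]) - L[m] / 2
        pts[m] = center[m] - axis[m] * s[:, None] - perp[m] * radius
        nrm[m] = -perp[m]
    m = arc >= a3
    if m.any():
        phi = (arc[m] - a3[m]) / radius
        tip = center[m] - axis[m] * (L[m] / 2)[:, None]
        n = (
            -np.cos(phi)[:, None] * perp[m]
            - np.sin(phi)[:, None] * axis[m]
        )
        pts[m] = tip + n * radius
        nrm[m] = n
    return pts, nrm


# ---------------------------------------------------------------------------
# firing schedules
# ---------------------------------------------------------------------------


def _random_needles(patch: PatchState, idx: int, count: int) -> list[Needle]:
    if count == 0:
        return []
    u = patch.rng.uniform(size=count)
    pts, nrm = surface_points(
        np.repeat(patch.center[idx][None], count, axis=0),
        np.repeat(patch.axis[idx][None], count, axis=0),
        np.repeat(patch.seg_length[idx], count),
        patch.params.R_cell,
        u,
    )
    cid = int(patch.ids[idx])
    return [
        Needle(cid, pts[k], nrm[k], patch.params.L_needle, patch.step_count)
        for k in range(count)
    ]


def schedule_firings(patch: PatchState, idx: int) -> list[Needle]:
    """Needles fired by the cell at array index ``idx`` this step.

    Lysing cells fire nothing.  R-types draw Poisson(k_fire*dt) random
    needles; retaliators answer their queued hits (multiplicity needles per
    hit, aimed back along the incoming direction, or from random surface
    sites for the aiming knockout); U and non-firing cheaters return [].
    Sets ``firings_last_step`` for the cell and clears its queue.
    """
    strat = patch.strategies[int(patch.genotype[idx])]
    cid = int(patch.ids[idx])
    if patch.lysing[idx] or not strat.carries_t6ss:
        patch.firings_last_step[idx] = 0
        patch.pending.pop(cid, None)
        return []
    needles: list[Needle] = []
    if strat.k_fire > 0:
        count = int(patch.rng.poisson(strat.k_fire * patch.params.dt))
        needles.extend(_random_needles(patch, idx, count))
    if strat.retaliation_multiplicity > 0:
        queued = patch.pending.pop(cid, [])
        if queued:
            if strat.aiming:
                for entry, direction in queued:
                    rev = -np.asarray(direction, float)
                    rev = rev / np.linalg.norm(rev)
                    for _ in range(strat.retaliation_multiplicity):
                        needles.append(
                            Needle(cid, np.asarray(entry, float).copy(), rev,
                                   patch.params.L_needle, patch.step_count)
                        )
            else:
                needles.extend(
                    _random_needles(
                        patch, idx, strat.retaliation_multiplicity * len(queued)
                    )
                )
    patch.firings_last_step[idx] = len(needles)
    return needles


def schedule_all_firings(patch: PatchState) -> list[Needle]:
    """All needles fired this step (engine path, batched Poisson draws).

    Constitutive firing counts for all eligible cells come from one
    vectorized Poisson draw; retaliation queues are then answered in
    insertion order.  Deterministic given the patch RNG state.
    """
    n = patch.n_cells
    needles: list[Needle] = []
    if n == 0:
        return needles
    patch.firings_last_step[:] = 0

    lam = np.zeros(n)
    for geno, strat in patch.strategies.items():
        if strat.carries_t6ss and strat.k_fire > 0:
            lam[patch.genotype == geno] = strat.k_fire * patch.params.dt
    lam[patch.lysing] = 0.0
    active = np.flatnonzero(lam > 0)
    if active.size:
        counts = patch.rng.poisson(lam[active])
        for idx, cnt in zip(active, counts):
            if cnt:
                needles.extend(_random_needles(patch, int(idx), int(cnt)))
                patch.firings_last_step[idx] = cnt

    if patch.pending:
        id_to_idx = {int(cid): k for k, cid in enumerate(patch.ids)}
        for cid in list(patch.pending):
            idx = id_to_idx.get(cid)
            if idx is None:
                patch.pending.pop(cid)
                continue
            strat = patch.strategies[int(patch.genotype[idx])]
            if patch.lysing[idx] or not strat.is_retaliator:
                patch.pending.pop(cid)
                continue
            queued = patch.pending.pop(cid)
            mult = strat.retaliation_multiplicity
            if strat.aiming:
                for entry, direction in queued:
                    rev = -np.asarray(direction, float)
                    rev = rev / np.linalg.norm(rev)
                    for _ in range(mult):
                        needles.append(Needle(cid, np.asarray(entry, float).copy(),
                                              rev, patch.params.L_needle,
                                              patch.step_count))
            else:
                needles.extend(_random_needles(patch, idx, mult * len(queued)))
            patch.firings_last_step[idx] += mult * len(queued)
    return needles


# ---------------------------------------------------------------------------
# hit detection
# ---------------------------------------------------------------------------


def _entry_params(O, U, A, ahat, L, R):
    """Smallest ray parameter s >= 0 at which O + s U crosses each capsule surface.

    Vectorized over candidate (needle, target) rows.  Returns s (inf where
    the ray never crosses within any finite parameter; caller bounds by
    needle length).  O: origins, U: unit directions, A: segment start
    points, ahat: unit axes, L: segment lengths, R: radius.
    """
    n = O.shape[0]
    s_best = np.full(n, np.inf)
    BIG = 1e30  # finite "never hits" placeholder; avoids inf*0 warnings

    W = O - A
    u_par = np.einsum("ij,ij->i", U, ahat)
    w_par = np.einsum("ij,ij->i", W, ahat)
    Uperp = U - u_par[:, None] * ahat
    Wperp = W - w_par[:, None] * ahat

    # point already inside the capsule (axis distance < R at s=0)
    # -> entry at the origin itself
    d0 = _point_seg_dist(O, A, ahat, L)
    inside = d0 < R
    s_best[inside] = 0.0

    # cylindrical flank: |Wperp + s Uperp|^2 = R^2 with axial foot in [0, L]
    a2 = np.einsum("ij,ij->i", Uperp, Uperp)
    b2 = 2 * np.einsum("ij,ij->i", Uperp, Wperp)
    c2 = np.einsum("ij,ij->i", Wperp, Wperp) - R * R
    disc = b2 * b2 - 4 * a2 * c2
    ok = (disc >= 0) & (a2 > 1e-14)
    sq = np.sqrt(np.where(ok, disc, 0.0))
    for sign in (-1.0, 1.0):
        s = np.where(ok, (-b2 + sign * sq) / (2 * np.where(ok, a2, 1.0)), BIG)
        foot = w_par + s * u_par
        valid = ok & (s >= -1e-12) & (foot >= -1e-12) & (foot <= L + 1e-12)
        s_best = np.where(valid & (s < s_best), np.maximum(s, 0.0), s_best)

    # spherical caps at both ends
    for end in (0.0, 1.0):
        Cc = A + (end * L)[:, None] * ahat
        Wc = O - Cc
        b3 = 2 * np.einsum("ij,ij->i", U, Wc)
        c3 = np.einsum("ij,ij->i", Wc, Wc) - R * R
        disc3 = b3 * b3 - 4 * c3
        ok3 = disc3 >= 0
        sq3 = np.sqrt(np.where(ok3, disc3, 0.0))
        for sign in (-1.0, 1.0):
            s = np.where(ok3, (-b3 + sign * sq3) / 2.0, BIG)
            pt_par = w_par + s * u_par  # axial coordinate of the point
            outside_seg = (pt_par <= 1e-12) if end == 0.0 else (pt_par >= L - 1e-12)
            valid = ok3 & (s >= -1e-12) & outside_seg
            s_best = np.where(valid & (s < s_best), np.maximum(s, 0.0), s_best)
    return s_best


def _point_seg_dist(P, A, ahat, L):
    w = P - A
    t = np.clip(np.einsum("ij,ij->i", w, ahat), 0.0, L)
    closest = A + t[:, None] * ahat
    return np.linalg.norm(P - closest, axis=1)


def detect_hits(needles: list[Needle], patch: PatchState) -> list[HitRecord]:
    """Resolve needle strikes: first cell entered along each needle.

    Candidate targets are cells (excluding the source) whose axis segment
    comes within ``R - L_penetration`` of the needle segment; among the
    candidates the needle hits the one whose surface entry point lies
    closest to the needle origin.  At most one record per needle.
    """
    if not needles or patch.n_cells == 0:
        return []
    p = patch.params
    R = p.R_cell
    K = len(needles)
    O = np.stack([nd.origin for nd in needles])
    Dir = np.stack([nd.direction for nd in needles])
    lengths = np.array([nd.length for nd in needles])
    src = np.array([nd.source_id for nd in needles])

    # broad phase: cells whose center is within reach of the needle midpoint
    mids = O[:, :2] + Dir[:, :2] * (lengths / 2)[:, None]
    cell_tree = cKDTree(patch.center[:, :2])
    reach = lengths.max() / 2 + float(np.max(patch.seg_length)) / 2 + R + 1e-9
    cand = cell_tree.query_ball_point(mids, r=reach)
    lens = np.fromiter((len(lst) for lst in cand), dtype=np.int64, count=K)
    if lens.sum() == 0:
        return []
    ni = np.repeat(np.arange(K), lens)
    ci = np.concatenate([np.asarray(lst, dtype=np.int64) for lst in cand if lst])
    not_self = patch.ids[ci] != src[ni]
    ni, ci = ni[not_self], ci[not_self]
    if ni.size == 0:
        return []

    # narrow phase test (i): needle segment vs cell axis segment distance
    from .mechanics import seg_seg_closest

    A = patch.center[ci] - patch.axis[ci] * patch.seg_length[ci, None] / 2
    Dseg = patch.axis[ci] * patch.seg_length[ci, None]
    _, _, _, _, dmin = seg_seg_closest(O[ni], Dir[ni] * lengths[ni, None], A, Dseg)
    passed = dmin < R - p.L_penetration
    if not passed.any():
        return []
    ni, ci = ni[passed], ci[passed]

    # test (ii): entry point = nearest surface intercept along the needle
    s = _entry_params(
        O[ni], Dir[ni], patch.center[ci] - patch.axis[ci] * patch.seg_length[ci, None] / 2,
        patch.axis[ci], patch.seg_length[ci], R,
    )
    within = s <= lengths[ni] + 1e-12
    ni, ci, s = ni[within], ci[within], s[within]
    if ni.size == 0:
        return []

    # needles stop at the first cell entered
    order = np.lexsort((s, ni))
    ni_o, ci_o, s_o = ni[order], ci[order], s[order]
    first = np.ones(ni_o.size, bool)
    first[1:] = ni_o[1:] != ni_o[:-1]

    id_to_gen = {int(cid): int(g) for cid, g in zip(patch.ids, patch.genotype)}
    records = []
    for k, cidx, sk in zip(ni_o[first], ci_o[first], s_o[first]):
        entry = O[k] + Dir[k] * sk
        tgt_gen = int(patch.genotype[cidx])
        src_gen = id_to_gen.get(int(src[k]), -1)
        records.append(
            HitRecord(
                needle=needles[k],
                target_id=int(patch.ids[cidx]),
                entry_point=entry,
                clonemate=(tgt_gen == src_gen),
            )
        )
    return records


# ---------------------------------------------------------------------------
# intoxication and lysis
# ---------------------------------------------------------------------------


def apply_intoxication(hits: list[HitRecord], patch: PatchState) -> PatchState:
    """Update translocation counts, lysis commitments and retaliation queues.

    A hit intoxicates unless shooter and target are clonemates or the target
    strategy's immunity set covers the shooter's genotype (mutual immunity).
    Every non-clonemate hit on a live retaliator — toxic or not — queues a
    counterattack: the trigger is membrane perturbation, not toxicity.
    """
    p = patch.params
    id_to_idx = {int(cid): k for k, cid in enumerate(patch.ids)}
    for hit in hits:
        tgt = id_to_idx.get(hit.target_id)
        if tgt is None:
            continue
        src_idx = id_to_idx.get(hit.needle.source_id)
        src_gen = int(patch.genotype[src_idx]) if src_idx is not None else -1
        tgt_gen = int(patch.genotype[tgt])
        strat = patch.strategies[tgt_gen]
        if hit.clonemate:
            patch.log("hit", source_id=hit.needle.source_id, target_id=hit.target_id,
                      source_genotype=src_gen, target_genotype=tgt_gen,
                      x=float(hit.entry_point[0]), y=float(hit.entry_point[1]),
                      intoxicating=False)
            continue
        immune = src_gen in strat.immune_to
        hit.intoxicating = not immune
        if hit.intoxicating:
            patch.translocations[tgt] += 1
            patch.log("intox", source_id=hit.needle.source_id,
                      target_id=hit.target_id, source_genotype=src_gen,
                      target_genotype=tgt_gen,
                      x=float(hit.entry_point[0]), y=float(hit.entry_point[1]))
            if (not patch.lysing[tgt]) and patch.translocations[tgt] >= p.N_hits:
                patch.lysing[tgt] = True
                patch.lysis_deadline[tgt] = patch.t + 1.0 / p.k_lysis
                patch.k_grow[tgt] = 0.0
                patch.log("lyse", target_id=hit.target_id, target_genotype=tgt_gen)
        else:
            patch.log("hit", source_id=hit.needle.source_id, target_id=hit.target_id,
                      source_genotype=src_gen, target_genotype=tgt_gen,
                      x=float(hit.entry_point[0]), y=float(hit.entry_point[1]),
                      intoxicating=False)
        if strat.is_retaliator and not patch.lysing[tgt]:
            patch.pending.setdefault(hit.target_id, []).append(
                (hit.entry_point.copy(), hit.needle.direction.copy())
            )
    return patch


def remove_lysed(patch: PatchState) -> PatchState:
    """Delete lysing cells whose deadline has arrived (closed interval)."""
    if patch.n_cells == 0:
        return patch
    doomed = patch.lysing & (patch.lysis_deadline <= patch.t + 1e-12)
    if not doomed.any():
        return patch
    for idx in np.flatnonzero(doomed):
        geno = int(patch.genotype[idx])
        patch.death_counts[geno] = patch.death_counts.get(geno, 0) + 1
        patch.log("death", cell_id=int(patch.ids[idx]), genotype=geno)
    patch.keep(~doomed)
    return patch
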