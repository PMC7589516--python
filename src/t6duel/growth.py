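"""Cell growth, division and zeroth-order resource depletion.

Volumes grow exponentially (dV/dt = k_grow V, integrated exactly per step),
with k_grow reduced below k_max by the costs of T6SS carriage and firing.
Cells divide lengthwise into two half-volume daughters once they exceed a
per-cell volume threshold 2 V_0 + eta drawn once at birth.  Living cells
deplete the shared patch resource E at rate k_max * sum(V); lysing cells
neither grow nor consume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .world import PatchState, StrategySpec, seg_length_for_volume

__all__ = [
    "CostAccount",
    "cost_fraction",
    "update_growth_rates",
    "grow_and_divide",
    "deplete_resources",
]


@dataclass(frozen=True)
class CostAccount:
    """Combined growth cost of a T6SS+ cell this step, clamped to [0, 1]."""

    c_upfront: float
    c: float
    n_firings_last: int
    c_total: float


def cost_fraction(strategy: StrategySpec, n_firings: int, dt: float,
                  c_upfront: float, c: float) -> CostAccount:
    """Growth-rate fraction lost to the T6SS: carriage plus pro-rata firing.

    Cost-saving strategists pay ``c * n_firings / dt`` (only for shots
    actually fired); the no-cost-saving knockout pays a flat ``c *
    k_fire_ref`` like a random firer of that reference rate, regardless of
    realized firings.  T6SS- cells pay nothing.
    """
    if not strategy.carries_t6ss:
        return CostAccount(0.0, c, int(n_firings), 0.0)
    if strategy.cost_saving:
        running = c * (n_firings / dt)
    else:
        running = c * strategy.k_fire_ref
    total = min(max(c_upfront + running, 0.0), 1.0)
    return CostAccount(c_upfront, c, int(n_firings), total)


def update_growth_rates(patch: PatchState) -> PatchState:
    """Set per-cell k_grow = k_max (1 - c_total); lysing cells do not grow."""
    p = patch.params
    k = np.full(patch.n_cells, p.k_max)
    for geno, strat in patch.strategies.items():
        if not strat.carries_t6ss:
            continue
        mask = patch.genotype == geno
        if not mask.any():
            continue
        if strat.cost_saving:
            running = p.c * (patch.firings_last_step[mask] / p.dt)
        else:
            running = p.c * strat.k_fire_ref
        c_total = np.clip(p.c_upfront + running, 0.0, 1.0)
        k[mask] = p.k_max * (1.0 - c_total)
    k[patch.lysing] = 0.0
    patch.k_grow = k
    return patch


def grow_and_divide(patch: PatchState) -> PatchState:
    """Exact one-step exponential growth, then lengthwise division.

    A dividing parent of volume V is replaced by two daughters of volume
    V/2 placed end-to-end along the parent axis so that their outer tips
    coincide with the parent's tips (the middle overlap is resolved by the
    mechanical relaxation).  Each daughter axis is rotated in-plane by an
    independent Uniform(-eta_orientations, +eta_orientations) angle.
    Daughters inherit genotype and translocation count; retaliation queues
    are cleared.  Total volume is conserved exactly at division.
    """
    p = patch.params
    if patch.n_cells == 0:
        return patch
    factor = np.exp(patch.k_grow * p.dt)
    patch.volume = patch.volume * factor
    patch.seg_length = seg_length_for_volume(patch.volume, p.R_cell)

    dividing = np.flatnonzero((patch.volume >= patch.div_threshold) & ~patch.lysing)
    if dividing.size == 0:
        return patch

    new_cols = {name: [] for name in PatchState._ARRAYS}
    rng = patch.rng
    for idx in dividing:
        V = patch.volume[idx]
        axis = patch.axis[idx]
        center = patch.center[idx]
        Vd = V / 2.0
        seg_d = seg_length_for_volume(Vd, p.R_cell)
        span_parent = patch.seg_length[idx] + 2 * p.R_cell
        span_d = seg_d + 2 * p.R_cell
        offset = (span_parent - span_d) / 2.0
        geno = patch.genotype[idx]
        for sign in (+1.0, -1.0):
            ang = rng.uniform(-p.eta_orientations, p.eta_orientations)
            cos, sin = math.cos(ang), math.sin(ang)
            d_axis = np.array([
                cos * axis[0] - sin * axis[1],
                sin * axis[0] + cos * axis[1],
                0.0,
            ])
            new_cols["ids"].append(patch.next_id)
            patch.next_id += 1
            new_cols["genotype"].append(geno)
            new_cols["center"].append(center + sign * offset * axis)
            new_cols["axis"].append(d_axis)
            new_cols["seg_length"].append(seg_d)
            new_cols["volume"].append(Vd)
            new_cols["div_threshold"].append(
                2 * p.V_0 + rng.uniform(0.0, p.eta_division)
            )
            new_cols["k_grow"].append(patch.k_grow[idx])
            new_cols["translocations"].append(patch.translocations[idx])
            new_cols["lysing"].append(False)
            new_cols["lysis_deadline"].append(math.inf)
            new_cols["firings_last_step"].append(0)
        patch.birth_counts[int(geno)] = patch.birth_counts.get(int(geno), 0) + 2
        patch.log("divide", cell_id=int(patch.ids[idx]), genotype=int(geno))

    keep = np.ones(patch.n_cells, bool)
    keep[dividing] = False
    # parents also leave the birth ledger (replaced, not dead)
    for idx in dividing:
        patch.birth_counts[int(patch.genotype[idx])] -= 1
    patch.keep(keep)
    patch.append_cells(**{k: np.asarray(v) for k, v in new_cols.items()})
    return patch


def deplete_resources(patch: PatchState) -> PatchState:
    """E <- E - k_max * sum(V over living non-lysing cells) * dt, floored at 0."""
    p = patch.params
    if patch.E <= 0:
        patch.E = 0.0
        patch.depleted = True
        return patch
    consumption = p.k_max * float(np.sum(patch.volume[~patch.lysing])) * p.dt
    patch.E = max(patch.E - consumption, 0.0)
    if patch.E == 0.0:
        patch.depleted = True
    return patch
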