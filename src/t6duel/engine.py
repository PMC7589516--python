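"""The per-step update loop, termination and trajectory recording.

A step applies, in order: firing (retaliations queued last step fire now),
hit detection, intoxication, removal of lysed cells, growth-rate update
(using this step's firing counts), growth and division, resource depletion,
mechanical relaxation, and the clock tick.  Runs terminate when the patch
resource E is depleted, or at ``max_steps`` (summary flagged censored).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import combat, growth, mechanics
from .world import PatchState, SimParams, make_initial_patch

__all__ = ["step", "run", "Trajectory"]


def step(patch: PatchState) -> PatchState:
    """Advance the patch by one timestep dt (in place; returns the patch)."""
    needles = combat.schedule_all_firings(patch)
    for nd in needles:
        patch.log("fire", source_id=nd.source_id,
                  x=float(nd.origin[0]), y=float(nd.origin[1]))
    hits = combat.detect_hits(needles, patch)
    combat.apply_intoxication(hits, patch)
    combat.remove_lysed(patch)
    growth.update_growth_rates(patch)
    growth.grow_and_divide(patch)
    growth.deplete_resources(patch)
    mechanics.relax(patch)
    patch.t += patch.params.dt
    patch.step_count += 1
    return patch


@dataclass
class Trajectory:
    """Result bundle of one patch run."""

    summary: dict
    events: pd.DataFrame
    snapshots: list = field(default_factory=list)  # (step, DataFrame) pairs
    final_patch: PatchState | None = None

    @property
    def censored(self) -> bool:
        return bool(self.summary.get("censored", False))


def run(
    params: SimParams,
    strategies,
    counts,
    seed,
    snapshot_every: int = 20,
    keep_events: bool = True,
) -> Trajectory:
    """Run one seeded patch competition until resource depletion.

    The summary records per-genotype initial/final cell counts and
    biovolumes (lysing cells excluded — they are committed dead), death and
    division tallies, and total biovolume at start and end.  Identical
    (params, strategies, counts, seed) give byte-identical summaries.
    """
    patch = make_initial_patch(params, strategies, counts, seed)
    strategies = list(strategies)
    init_counts = patch.genotype_counts()
    init_vol = patch.genotype_biovolume()
    snapshots = []
    if snapshot_every:
        snapshots.append((0, patch.to_dataframe()))

    while (not patch.depleted) and patch.step_count < params.max_steps and patch.n_cells:
        step(patch)
        if snapshot_every and patch.step_count % snapshot_every == 0:
            snapshots.append((patch.step_count, patch.to_dataframe()))
    censored = (not patch.depleted) and patch.n_cells > 0

    final_counts = patch.genotype_counts()
    final_vol = patch.genotype_biovolume()
    summary = {
        "t_end": patch.t,
        "steps": patch.step_count,
        "E_final": patch.E,
        "censored": censored,
        "seed": int(seed),
        "genotypes": sorted(patch.strategies),
        "strategy_names": {g: s.name for g, s in patch.strategies.items()},
        "initial_counts": init_counts,
        "final_counts": final_counts,
        "initial_biovolume": init_vol,
        "final_biovolume": final_vol,
        "total_biovolume_start": sum(init_vol.values()),
        "total_biovolume_end": sum(final_vol.values()),
        "death_counts": dict(patch.death_counts),
        "birth_counts": dict(patch.birth_counts),
    }
    events = pd.DataFrame(patch.events) if keep_events else pd.DataFrame()
    if snapshot_every and (not snapshots or snapshots[-1][0] != patch.step_count):
        snapshots.append((patch.step_count, patch.to_dataframe()))
    return Trajectory(summary=summary, events=events, snapshots=snapshots,
                      final_patch=patch)
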