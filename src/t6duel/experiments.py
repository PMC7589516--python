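"""Reproducible experiment presets wiring the simulator to the analysis layer.

Every sweep row carries the content hash of its resolved configuration plus
the seed that produced it, so any figure-style CSV can be regenerated
bit-identically from (preset, overrides, seeds).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict

import numpy as np
import pandas as pd

from . import engine, metrics
from .invasion import FitnessTable
from .world import SimParams, StrategySpec, strategy_presets

__all__ = [
    "competition",
    "build_fitness_table",
    "preset_sweep",
    "provenance_stamp",
    "PRESETS",
]

log = logging.getLogger(__name__)


def _immunized(a: StrategySpec, b: StrategySpec) -> tuple:
    """Return the pair with mutual immunity added (the primed pairing)."""
    a2 = StrategySpec(**{**asdict(a), "immune_to": frozenset(a.immune_to) | {b.genotype}})
    b2 = StrategySpec(**{**asdict(b), "immune_to": frozenset(b.immune_to) | {a.genotype}})
    return a2, b2


def competition(params: SimParams, strat_a: StrategySpec, strat_b: StrategySpec,
                counts, seed, primed: bool = False, snapshot_every: int = 0):
    """Run one A-vs-B patch competition; returns the Trajectory.

    ``primed=True`` simulates the mutually immune pairing (T6SS attacks
    between the two genotypes have no toxic effect; retaliation triggers
    are unaffected).
    """
    if primed:
        strat_a, strat_b = _immunized(strat_a, strat_b)
    return engine.run(params, [strat_a, strat_b], counts, seed,
                      snapshot_every=snapshot_every)


def build_fitness_table(params: SimParams, pairings, counts, seeds,
                        table: FitnessTable | None = None) -> FitnessTable:
    """Simulate replicate competitions and collect omega entries.

    ``pairings`` is an iterable of (strat_a, strat_b, primed) triples; for
    each, every seed in ``seeds`` contributes one replicate of
    omega_A(A|B[']) and omega_B(B-side).  Labels are the strategy names.
    """
    table = table if table is not None else FitnessTable()
    for strat_a, strat_b, primed in pairings:
        for seed in seeds:
            traj = competition(params, strat_a, strat_b, counts, seed, primed=primed)
            s = traj.summary
            wa = metrics.strategist_fitness(s, strat_a.genotype)
            wb = metrics.strategist_fitness(s, strat_b.genotype)
            table.add(strat_a.name, strat_b.name, wa, primed=primed)
            table.add(strat_b.name, strat_a.name, wb, primed=primed)
    return table


def r_vs_r_simulator(params: SimParams, counts, primed: bool = False):
    """Adapter for pairwise-invasibility sweeps between two random firers.

    Returns ``simulator(k_res, k_mut, seed)`` producing the omega entries
    the PIP builder needs.  The resident self-competition (needed for the
    global scale) pairs two strains with the resident rate.
    """
    presets = strategy_presets()

    def simulate(k_res: float, k_mut: float, seed: int) -> dict:
        res = presets["R"](0, k_fire=k_res)
        mut = presets["R"](1, k_fire=k_mut)
        traj = competition(params, res, mut, counts, seed, primed=primed)
        out = {
            "w_res_mixed": metrics.strategist_fitness(traj.summary, 0),
            "w_mut_mixed": metrics.strategist_fitness(traj.summary, 1),
        }
        res2 = presets["R"](1, k_fire=k_res)
        traj_self = competition(params, res, res2, counts, seed + 1, primed=primed)
        out["w_res_self"] = metrics.strategist_fitness(traj_self.summary, 0)
        return out

    return simulate


# ---------------------------------------------------------------------------
# provenance
# ---------------------------------------------------------------------------


def _canonical(obj):
    if isinstance(obj, dict):
        return {str(k): _canonical(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
    if isinstance(obj, (list, tuple)):
        return [_canonical(v) for v in obj]
    if isinstance(obj, (set, frozenset)):
        return sorted(_canonical(v) for v in obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if hasattr(obj, "__dataclass_fields__"):
        return _canonical(asdict(obj))
    return obj


def provenance_stamp(config) -> str:
    """Stable content hash of a resolved configuration (key-order invariant)."""
    payload = json.dumps(_canonical(config), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------


def _preset_rvu_density(params: SimParams, overrides: dict, seeds) -> pd.DataFrame:
    densities = overrides.get("densities", (10, 50, 100))
    k_fire = overrides.get("k_fire", 50.0)
    presets = strategy_presets()
    R = presets["R"](0, k_fire=k_fire)
    U = presets["U"](1)
    stamp = provenance_stamp({"preset": "RvU_density", "params": params,
                              "densities": list(densities), "k_fire": k_fire})
    rows = []
    for n in densities:
        for seed in seeds:
            traj = competition(params, R, U, (n, n), seed)
            rows.append({
                "preset": "RvU_density", "density": n, "k_fire": k_fire,
                "seed": seed, "config_hash": stamp,
                "final_R_proportion": metrics.final_proportion(traj.summary, 0),
                "omega_R": metrics.strategist_fitness(traj.summary, 0),
                "omega_U": metrics.strategist_fitness(traj.summary, 1),
                "censored": traj.summary["censored"],
            })
    return pd.DataFrame(rows)


def _preset_retaliator(name: str, retaliator_key: str):
    def build(params: SimParams, overrides: dict, seeds) -> pd.DataFrame:
        rates = overrides.get("k_fire_grid", (25.0, 50.0, 100.0))
        n = overrides.get("density", 200)
        presets = strategy_presets()
        stamp = provenance_stamp({"preset": name, "params": params,
                                  "rates": list(rates), "density": n})
        rows = []
        for k_fire in rates:
            R = presets["R"](0, k_fire=k_fire)
            Y = presets[retaliator_key](1)
            for seed in seeds:
                traj = competition(params, R, Y, (n, n), seed)
                rows.append({
                    "preset": name, "density": n, "k_fire": k_fire,
                    "seed": seed, "config_hash": stamp,
                    "final_R_proportion": metrics.final_proportion(traj.summary, 0),
                    "final_retaliator_proportion": metrics.final_proportion(traj.summary, 1),
                    "omega_R": metrics.strategist_fitness(traj.summary, 0),
                    "omega_retaliator": metrics.strategist_fitness(traj.summary, 1),
                    "censored": traj.summary["censored"],
                })
        return pd.DataFrame(rows)

    return build


def _preset_knockout_grid(params: SimParams, overrides: dict, seeds) -> pd.DataFrame:
    """2x2 grid of 2TFT variants: aiming and cost saving each on/off."""
    k_fire = overrides.get("k_fire", 50.0)
    n = overrides.get("density", 100)
    presets = strategy_presets()
    stamp = provenance_stamp({"preset": "knockout_grid", "params": params,
                              "k_fire": k_fire, "density": n})
    rows = []
    for aiming in (True, False):
        for cost_saving in (True, False):
            R = presets["R"](0, k_fire=k_fire)
            Y = StrategySpec("2TFT", 1, retaliation_multiplicity=2,
                             aiming=aiming, cost_saving=cost_saving,
                             k_fire_ref=0.0 if cost_saving else k_fire)
            for seed in seeds:
                traj = competition(params, R, Y, (n, n), seed)
                rows.append({
                    "preset": "knockout_grid", "aiming": aiming,
                    "cost_saving": cost_saving, "k_fire": k_fire,
                    "density": n, "seed": seed, "config_hash": stamp,
                    "final_R_proportion": metrics.final_proportion(traj.summary, 0),
                    "final_retaliator_proportion": metrics.final_proportion(traj.summary, 1),
                    "censored": traj.summary["censored"],
                })
    return pd.DataFrame(rows)


PRESETS = {
    "RvU_density": _preset_rvu_density,
    "RvTFT": _preset_retaliator("RvTFT", "TFT"),
    "Rv2TFT": _preset_retaliator("Rv2TFT", "2TFT"),
    "knockout_grid": _preset_knockout_grid,
}


def preset_sweep(name: str, overrides: dict | None = None, seeds=(0,),
                 params: SimParams | None = None) -> pd.DataFrame:
    """Run a named competition sweep; returns a tidy DataFrame of outcomes.

    Every row carries the resolved-config hash and the seed.  Zero seeds
    yield an empty frame with a warning.
    """
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    overrides = dict(overrides or {})
    params = params if params is not None else SimParams(E_0=overrides.pop("E_0", 1500.0))
    seeds = list(seeds)
    if not seeds:
        log.warning("preset %s invoked with zero seeds; empty result", name)
        return pd.DataFrame()
    return PRESETS[name](params, overrides, seeds)
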